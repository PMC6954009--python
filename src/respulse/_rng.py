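"""Named random substreams from one root seed.

Every stochastic component (network draw, growth-rate field, disturbance
placement, ...) pulls its own generator from the root seed plus a purpose
name, so varying one component never perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *names: str | int) -> np.random.Generator:
    """Generator for the substream identified by ``names`` under ``seed``.

    Names (strings or small integers, e.g. a replicate index) are hashed
    into the seed sequence, so ``substream(s, "r-field", 3)`` is stable
    across runs and independent of ``substream(s, "disturbance", 3)``.
    """
    keys = [int(seed) & 0x7FFFFFFF]
    for name in names:
        if isinstance(name, str):
            keys.append(zlib.crc32(name.encode()) & 0x7FFFFFFF)
        else:
            keys.append(int(name) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(keys))
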