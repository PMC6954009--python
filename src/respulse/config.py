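"""Run-configuration parsing and validation.

A single YAML file configures every entry point, with sections
``model`` / ``landscape`` / ``disturbance`` / ``sweep`` / ``solver`` /
``output`` plus a top-level ``seed``.  Every field has a documented
default; unknown keys are rejected so typos fail loudly.  Command-line
flags override file values, which override defaults.
"""

from __future__ import annotations

import copy
import json
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from respulse.disturbance import DisturbanceSpec
from respulse.dynamics import IntegrationControl
from respulse.experiments import SweepConfig, default_c_grid
from respulse.landscapes import HeterogeneitySpec
from respulse.local_model import LocalParams

__all__ = ["RunConfig", "load_config", "atomic_write_text"]

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "model": {"r": 1.0, "K": 10.0, "H": 1.0, "c": 2.0},
    "landscape": {
        "kind": "continuous",
        "dispersal": 2.5,
        "n_x": 50, "n_y": 50, "cell_size": 2.0,
        "n_patches": 100, "edge_probability": 0.04,
        "boundary": "zero-flux",
        "heterogeneity": None,
    },
    "disturbance": {"kind": "square_local", "size": 0.01, "location": "center"},
    "sweep": {
        "c_start": 1.8, "c_stop": 2.8, "c_step": 0.05,
        "replicates": 1, "mode": "standardized",
        "random_size_range": [0.01, 0.05],
        "scenario": "",
    },
    "solver": {
        "t_max": 10_000.0, "rel_tol": 1e-8, "abs_tol": 1e-10,
        "steady_state_epsilon": 1e-6, "record_interval": 1.0,
    },
    "output": {"directory": "respulse-out", "verbosity": "info"},
}

_HET_KEYS = {"block_grid", "r_low", "r_high", "sigma_m", "truncate"}


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {where}")
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge(defaults[key], val, where)
        else:
            out[key] = val
    return out


@dataclass
class RunConfig:
    """Validated union of all module configurations."""

    raw: dict[str, Any]

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def params(self) -> LocalParams:
        m = self.raw["model"]
        return LocalParams(r=m["r"], K=m["K"], c=m["c"], H=m["H"])

    @property
    def control(self) -> IntegrationControl:
        return IntegrationControl(**self.raw["solver"])

    @property
    def disturbance(self) -> DisturbanceSpec:
        d = self.raw["disturbance"]
        loc = d["location"]
        if isinstance(loc, list):
            loc = tuple(loc)
        return DisturbanceSpec(kind=d["kind"], size=d["size"], location=loc)

    @property
    def heterogeneity(self) -> HeterogeneitySpec | None:
        h = self.raw["landscape"]["heterogeneity"]
        if h is None:
            return None
        extra = set(h) - _HET_KEYS
        if extra:
            raise ConfigError(f"unknown heterogeneity keys: {sorted(extra)}")
        return HeterogeneitySpec(**h)

    @property
    def output_dir(self) -> Path:
        return Path(self.raw["output"]["directory"])

    def sweep_config(self) -> SweepConfig:
        ls, sw = self.raw["landscape"], self.raw["sweep"]
        return SweepConfig(
            landscape=ls["kind"],
            dispersal=ls["dispersal"],
            disturbance=self.disturbance,
            c_grid=tuple(default_c_grid(sw["c_start"], sw["c_stop"], sw["c_step"])),
            replicates=sw["replicates"],
            heterogeneity=self.heterogeneity,
            params=self.params,
            n_x=ls["n_x"], n_y=ls["n_y"], cell_size=ls["cell_size"],
            n_patches=ls["n_patches"], edge_probability=ls["edge_probability"],
            seed=self.seed,
            control=self.control,
            scenario=sw["scenario"],
            random_size_range=tuple(sw["random_size_range"]),
        )

    def manifest(self) -> str:
        from respulse import __version__
        return json.dumps(
            {"config": self.raw, "version": __version__}, indent=2, default=str
        )


def load_config(
    path: str | Path | None = None,
    overrides: dict[str, Any] | None = None,
) -> RunConfig:
    """Load, merge with defaults, and validate a configuration.

    ``overrides`` maps dotted keys (``"landscape.dispersal"``) to values,
    applied after the file.
    """
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("configuration root must be a mapping")
    merged = _merge(_DEFAULTS, user)
    for dotted, value in (overrides or {}).items():
        node = merged
        parts = dotted.split(".")
        for part in parts[:-1]:
            if part not in node or not isinstance(node[part], dict):
                raise ConfigError(f"unknown configuration key: {dotted}")
            node = node[part]
        if parts[-1] not in node:
            raise ConfigError(f"unknown configuration key: {dotted}")
        node[parts[-1]] = value
    return RunConfig(raw=merged)


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write via a temp file and rename, so readers never see partials."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)
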