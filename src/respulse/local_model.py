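"""Non-spatial harvested-resource model with alternative stable states.

The local dynamics follow the classic grazing/harvesting model: logistic
growth of a resource ``N`` (biomass, g m^-2) harvested with a sigmoidal
(Holling type III) functional response,

    f(N) = r N (1 - N/K) - c N^2 / (N^2 + H^2)

For intermediate maximum harvest rates ``c`` the model is bistable: a high
(underexploited) and a low (overexploited) stable state coexist, separated
by an unstable equilibrium.  Raising ``c`` erodes the high state until it
vanishes in a saddle-node (fold) bifurcation — the tipping point for
system-wide collapse.  Between the two folds lies the Maxwell point, the
harvest rate at which the two stable states have equal potential; beyond
it a large enough local perturbation can nucleate a travelling front to
the low state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "LocalParams",
    "Equilibrium",
    "EquilibriumSet",
    "BifurcationSummary",
    "growth_rate",
    "growth_derivative",
    "potential",
    "find_equilibria",
    "scan_folds",
    "maxwell_point",
    "bifurcation_summary",
    "MonostableError",
]

#: |f'(N)| below this at a root -> stability reported as "marginal"
_MARGINAL_TOL = 1e-7
#: residual tolerance for refined roots
_ROOT_TOL = 1e-10


class MonostableError(ValueError):
    """Raised when an operation requires a bistable parameter regime."""


@dataclass(frozen=True)
class LocalParams:
    """Parameters of the local growth-harvest balance.

    Attributes
    ----------
    r : float
        Maximum per-capita growth rate (day^-1).
    K : float
        Carrying capacity (g m^-2).
    c : float
        Maximum harvest rate (g m^-2 day^-1).
    H : float
        Half-saturation biomass of the harvesting response (g m^-2).
    """

    r: float = 1.0
    K: float = 10.0
    c: float = 2.0
    H: float = 1.0

    def __post_init__(self) -> None:
        for name in ("r", "K", "c", "H"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        # c = 0 is permitted (pure logistic); the other three must be positive
        for name in ("r", "K", "H"):
            if getattr(self, name) == 0:
                raise ValueError(f"{name} must be strictly positive")

    def with_c(self, c: float) -> "LocalParams":
        return replace(self, c=c)

    def with_r(self, r: float) -> "LocalParams":
        return replace(self, r=r)


@dataclass(frozen=True)
class Equilibrium:
    biomass: float
    stability: Literal["stable", "unstable", "marginal"]


@dataclass(frozen=True)
class EquilibriumSet:
    """All non-negative equilibria of the local model, sorted ascending."""

    equilibria: tuple[Equilibrium, ...]

    def __iter__(self):
        return iter(self.equilibria)

    def __len__(self) -> int:
        return len(self.equilibria)

    @property
    def stable(self) -> tuple[float, ...]:
        return tuple(e.biomass for e in self.equilibria if e.stability == "stable")

    @property
    def unstable(self) -> tuple[float, ...]:
        return tuple(e.biomass for e in self.equilibria if e.stability == "unstable")

    @property
    def high_state(self) -> float | None:
        """Largest stable equilibrium, or None if none exists."""
        return max(self.stable) if self.stable else None

    @property
    def low_state(self) -> float | None:
        """Smallest stable equilibrium, or None if none exists."""
        return min(self.stable) if self.stable else None

    @property
    def threshold(self) -> float | None:
        """Largest positive unstable equilibrium (basin boundary), if any."""
        pos = [u for u in self.unstable if u > _ROOT_TOL]
        return max(pos) if pos else None

    def is_bistable(self) -> bool:
        return len(self.stable) >= 2


def growth_rate(N, p: LocalParams):
    """Net local growth f(N) = rN(1 - N/K) - cN^2/(N^2 + H^2).

    Accepts scalars or arrays; biomass must be non-negative.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("biomass must be non-negative")
    out = _growth_unchecked(N, p)
    return float(out) if out.ndim == 0 else out


def _growth_unchecked(N, p: LocalParams):
    # used inside the spatial right-hand sides, where the solver may probe
    # states a rounding error below zero
    N = np.asarray(N, dtype=float)
    return p.r * N * (1.0 - N / p.K) - p.c * N * N / (N * N + p.H * p.H)


def growth_derivative(N, p: LocalParams):
    """Analytic df/dN = r(1 - 2N/K) - 2cNH^2/(N^2 + H^2)^2."""
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("biomass must be non-negative")
    s = N * N + p.H * p.H
    out = p.r * (1.0 - 2.0 * N / p.K) - 2.0 * p.c * N * p.H * p.H / (s * s)
    return float(out) if out.ndim == 0 else out


def potential(N, p: LocalParams):
    """Potential V(N) = -int_0^N f(s) ds (closed form).

    The dynamics are gradient: N' = -dV/dN.  Wells of V are the stable
    states; at the Maxwell point the two wells are equally deep.
    """
    N = np.asarray(N, dtype=float)
    logistic = p.r * (N * N / 2.0 - N ** 3 / (3.0 * p.K))
    harvest = p.c * (N - p.H * np.arctan(N / p.H))
    out = -(logistic - harvest)
    return float(out) if out.ndim == 0 else out


def find_equilibria(p: LocalParams, n_scan: int = 10_000) -> EquilibriumSet:
    """Locate all non-negative roots of f and classify their stability.

    A dense scan of [0, 1.5 K] brackets sign changes which are refined by
    Brent's method; N = 0 is always an equilibrium.  Stability follows the
    sign of f'(N); a derivative within tolerance of zero (exactly at a
    fold) is reported as "marginal".
    """
    f = lambda N: _growth_unchecked(np.asarray(N), p)
    grid = np.linspace(0.0, 1.5 * p.K, n_scan)
    vals = f(grid)

    roots = [0.0]
    for i in range(len(grid) - 1):
        a, b = grid[i], grid[i + 1]
        fa, fb = vals[i], vals[i + 1]
        if fa == 0.0 and a > 0:
            roots.append(a)
        elif fa * fb < 0:
            roots.append(brentq(f, a, b, xtol=_ROOT_TOL, rtol=8.9e-16))
    if vals[-1] == 0.0:
        roots.append(grid[-1])

    # dedupe (0 may re-appear from the first interval)
    roots = sorted(roots)
    uniq: list[float] = []
    for root in roots:
        if not uniq or root - uniq[-1] > 1e-8:
            uniq.append(root)

    eqs = []
    for root in uniq:
        d = growth_derivative(root, p)
        if abs(d) < _MARGINAL_TOL:
            stab = "marginal"
        elif d < 0:
            stab = "stable"
        else:
            stab = "unstable"
        eqs.append(Equilibrium(biomass=root, stability=stab))
    return EquilibriumSet(equilibria=tuple(eqs))


def _n_positive_equilibria(c: float, p: LocalParams, n_scan: int = 4000) -> int:
    # fast count: sign changes of f on a dense positive grid (no refinement)
    grid = np.linspace(1e-9, 1.5 * p.K, n_scan)
    vals = _growth_unchecked(grid, p.with_c(c))
    sign = np.sign(vals)
    return int(np.count_nonzero(sign[:-1] * sign[1:] < 0))


def scan_folds(
    p: LocalParams,
    c_range: tuple[float, float] = (0.5, 4.0),
    resolution: float = 1e-3,
) -> tuple[float, float]:
    """Locate the two saddle-node bifurcations in the harvest rate c.

    Scans ``c_range`` on a grid of the given resolution, finds where the
    number of positive equilibria switches between one and three, and
    refines each transition by bisection to 1e-6.  Returns
    ``(c_fold_low, c_fold_high)``.

    Raises
    ------
    MonostableError
        If no c in the range yields three positive equilibria.
    """
    c_lo, c_hi = c_range
    n = max(2, int(np.ceil((c_hi - c_lo) / resolution)) + 1)
    cs = np.linspace(c_lo, c_hi, n)
    counts = np.array([_n_positive_equilibria(c, p) for c in cs])
    tri = np.flatnonzero(counts >= 3)
    if tri.size == 0:
        raise MonostableError(
            f"no bistable region found for c in [{c_lo}, {c_hi}] at {p}"
        )

    def bisect_transition(c_mono: float, c_bi: float) -> float:
        # boundary between a c with <3 and a c with >=3 positive equilibria
        for _ in range(60):
            mid = 0.5 * (c_mono + c_bi)
            if _n_positive_equilibria(mid, p) >= 3:
                c_bi = mid
            else:
                c_mono = mid
            if abs(c_bi - c_mono) < 1e-6:
                break
        return 0.5 * (c_mono + c_bi)

    i0, i1 = tri[0], tri[-1]
    c_fold_low = cs[i0] if i0 == 0 else bisect_transition(cs[i0 - 1], cs[i0])
    c_fold_high = cs[i1] if i1 == n - 1 else bisect_transition(cs[i1 + 1], cs[i1])
    return float(c_fold_low), float(c_fold_high)


def maxwell_point(
    p: LocalParams,
    c_range: tuple[float, float] = (0.5, 4.0),
    tol: float = 1e-8,
) -> float:
    """Harvest rate at which the two stable states have equal potential.

    Solves int_{N_low}^{N_high} f(N) dN = 0 (potential difference between
    the outer stable states) by bisection in c over the bistable interval,
    with adaptive quadrature for the integral.
    """
    c_lo, c_hi = scan_folds(p, c_range=c_range)

    def area(c: float) -> float:
        eqs = find_equilibria(p.with_c(c))
        stable = eqs.stable
        if len(stable) < 2:
            raise MonostableError(f"c={c} is not bistable")
        n_low, n_high = min(stable), max(stable)
        val, _ = quad(lambda N: _growth_unchecked(np.asarray(N), p.with_c(c)),
                      n_low, n_high, epsabs=tol, epsrel=tol, limit=200)
        return val

    # area > 0 -> high state favoured (c too small); shrink toward folds
    # slightly so both endpoints are strictly bistable
    eps = 1e-5 * (c_hi - c_lo)
    a, b = c_lo + eps, c_hi - eps
    fa, fb = area(a), area(b)
    if fa * fb > 0:
        raise MonostableError("potential difference does not change sign between folds")
    for _ in range(200):
        mid = 0.5 * (a + b)
        fm = area(mid)
        if fa * fm <= 0:
            b, fb = mid, fm
        else:
            a, fa = mid, fm
        if b - a < tol:
            break
    return 0.5 * (a + b)


@dataclass(frozen=True)
class BifurcationSummary:
    """Fold and Maxwell harvest rates for one (r, K, H) parameter set."""

    c_fold_low: float
    c_fold_high: float
    c_maxwell: float
    params: LocalParams

    def __post_init__(self) -> None:
        if not (self.c_fold_low < self.c_maxwell < self.c_fold_high):
            raise ValueError("Maxwell point must lie strictly between the folds")

    def to_json(self, **dump_kwargs) -> str:
        rec = {
            "c_fold_low": self.c_fold_low,
            "c_fold_high": self.c_fold_high,
            "c_maxwell": self.c_maxwell,
            "params": {"r": self.params.r, "K": self.params.K, "H": self.params.H},
        }
        return json.dumps(rec, **dump_kwargs)


def bifurcation_summary(
    p: LocalParams,
    c_range: tuple[float, float] = (0.5, 4.0),
    resolution: float = 1e-3,
) -> BifurcationSummary:
    """Compute folds and Maxwell point in one call."""
    lo, hi = scan_folds(p, c_range=c_range, resolution=resolution)
    cm = maxwell_point(p, c_range=c_range)
    return BifurcationSummary(c_fold_low=lo, c_fold_high=hi, c_maxwell=cm, params=p)
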