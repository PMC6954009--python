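"""Time integration of the spatial systems.

Both landscapes evolve under `state' = local growth + dispersal`:
method-of-lines reaction-diffusion on the grid (5-point Laplacian,
zero-flux boundaries by default) and coupled patch ODEs on the network.
Integration uses an explicit adaptive embedded Runge-Kutta 4(5) scheme
(scipy's RK45) with terminal event detection for recovery, collapse and
steady state, so trajectories stop as soon as their outcome is decided
and event times are located by the solver's root finder rather than by
snapshot spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from respulse.local_model import (
    LocalParams,
    _growth_unchecked,
    find_equilibria,
)
from respulse.landscapes import ContinuousLandscape, PatchyLandscape

__all__ = [
    "IntegrationControl",
    "Trajectory",
    "EventSpec",
    "laplacian_term",
    "continuous_rhs",
    "patchy_rhs",
    "make_rhs",
    "integrate",
    "steady_state_event",
    "settle_to_equilibrium",
    "NoHighStateError",
]

Landscape = ContinuousLandscape | PatchyLandscape


class NoHighStateError(RuntimeError):
    """The landscape has no high-biomass attractor at these parameters."""


@dataclass(frozen=True)
class IntegrationControl:
    """Solver and termination settings.

    ``steady_state_epsilon`` is the max-norm of the time derivative
    (g m^-2 day^-1) below which the state counts as stationary; about
    1e-5 of the scale of the local growth term over the bistable range.
    The solver tolerances are chosen so the numerical residual floor near
    an attractor (roughly rel_tol times the biomass scale) sits safely
    below that epsilon; looser tolerances would keep the steady-state
    criterion from ever being met.
    """

    t_max: float = 10_000.0          # days
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    steady_state_epsilon: float = 1e-6
    record_interval: float = 1.0     # days between stored snapshots

    def __post_init__(self) -> None:
        for name in ("t_max", "rel_tol", "abs_tol", "steady_state_epsilon",
                     "record_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EventSpec:
    """Named terminal/non-terminal event for the ODE solver."""

    name: str
    fn: Callable[[float, np.ndarray], float]
    terminal: bool = True
    direction: float = 0.0

    def __call__(self, t: float, y: np.ndarray) -> float:
        return self.fn(t, y)


@dataclass
class Trajectory:
    """Recorded time course of one integration.

    ``states`` holds one flattened landscape state per snapshot; the last
    row is the terminal state (event-located when an event fired).
    ``monitor_index`` selects the monitored site; None means the spatial
    mean is monitored.
    """

    times: np.ndarray                 # (n_t,), days
    states: np.ndarray                # (n_t, n_sites)
    monitor_index: int | None = None
    event_times: dict[str, float] = field(default_factory=dict)
    terminated_by: str | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.min(self.states) < -1e-9:
            raise ValueError("negative biomass beyond numerical tolerance")

    @property
    def monitored_site_series(self) -> np.ndarray:
        if self.monitor_index is None:
            return self.spatial_mean_series
        return self.states[:, self.monitor_index]

    @property
    def spatial_mean_series(self) -> np.ndarray:
        return self.states.mean(axis=1)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    @property
    def t_final(self) -> float:
        return float(self.times[-1])

    def to_long_frame(self):
        """Long-format table (time, site, biomass), one row per snapshot
        per site — the on-disk trajectory exchange format."""
        import pandas as pd

        n_t, n_sites = self.states.shape
        return pd.DataFrame({
            "time": np.repeat(self.times, n_sites),
            "site": np.tile(np.arange(n_sites), n_t),
            "biomass": self.states.ravel(),
        })


def laplacian_term(
    biomass: np.ndarray,
    cell_size: float,
    D: float,
    boundary: str = "zero-flux",
) -> np.ndarray:
    """Diffusion term: 5-point finite-difference Laplacian times D.

    Zero-flux boundaries mirror the edge cell into the ghost cell, so the
    term sums to zero over the domain (no biomass enters or leaves).
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    N = np.asarray(biomass, dtype=float)
    mode = "edge" if boundary == "zero-flux" else "wrap"
    p = np.pad(N, 1, mode=mode)
    lap = p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * N
    return D / cell_size**2 * lap


def continuous_rhs(landscape: ContinuousLandscape) -> np.ndarray:
    """Time derivative field: per-cell growth (with per-cell r) + diffusion."""
    p = landscape.params
    N = landscape.biomass
    growth = _growth_unchecked(N, p) + (landscape.r_field - p.r) * N * (1.0 - N / p.K)
    return growth + laplacian_term(N, landscape.cell_size, landscape.D,
                                   landscape.boundary)


def patchy_rhs(landscape: PatchyLandscape) -> np.ndarray:
    """Time derivative vector: per-patch growth + d * sum_j (N_j - N_i)."""
    p = landscape.params
    N = landscape.biomass
    growth = _growth_unchecked(N, p) + (landscape.r_vec - p.r) * N * (1.0 - N / p.K)
    coupling = landscape.d * (landscape.adjacency @ N - landscape.degrees * N)
    return growth + coupling


def make_rhs(landscape: Landscape) -> Callable[[float, np.ndarray], np.ndarray]:
    """Flat-vector right-hand side for the ODE solver (no state copies)."""
    p = landscape.params
    if isinstance(landscape, ContinuousLandscape):
        shape = landscape.biomass.shape
        r_dev = landscape.r_field - p.r
        cell_size, D, bnd = landscape.cell_size, landscape.D, landscape.boundary

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            N = y.reshape(shape)
            out = _growth_unchecked(N, p) + r_dev * N * (1.0 - N / p.K)
            out += laplacian_term(N, cell_size, D, bnd)
            return out.ravel()

        return rhs

    adj, deg, d = landscape.adjacency, landscape.degrees, landscape.d
    r_dev = landscape.r_vec - p.r

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        out = _growth_unchecked(y, p) + r_dev * y * (1.0 - y / p.K)
        out += d * (adj @ y - deg * y)
        return out

    return rhs


def steady_state_event(landscape: Landscape, control: IntegrationControl) -> EventSpec:
    """Terminal event: max-norm of the time derivative falls below epsilon."""
    rhs = make_rhs(landscape)
    eps = control.steady_state_epsilon
    return EventSpec(
        name="steady_state",
        fn=lambda t, y: float(np.max(np.abs(rhs(t, y)))) - eps,
        terminal=True,
        direction=-1.0,
    )


def integrate(
    landscape: Landscape,
    control: IntegrationControl | None = None,
    stop_events: Sequence[EventSpec] = (),
    monitor_index: int | None = None,
) -> Trajectory:
    """Integrate from the landscape's current state.

    Runs to ``control.t_max`` or until the first terminal event fires;
    snapshots are stored every ``record_interval`` days plus the exact
    terminal state.  Tiny negative excursions from the solver are clipped
    at -1e-9 (the non-negativity tolerance).
    """
    control = control or IntegrationControl()
    rhs = make_rhs(landscape)
    y0 = np.asarray(landscape.biomass, dtype=float).ravel().copy()

    # EventSpec instances are callables carrying the .terminal/.direction
    # attributes solve_ivp inspects
    events = list(stop_events)

    t_eval = np.concatenate(
        [np.arange(0.0, control.t_max, control.record_interval), [control.t_max]]
    )

    sol = solve_ivp(
        rhs,
        (0.0, control.t_max),
        y0,
        method="RK45",
        t_eval=t_eval,
        events=events or None,
        rtol=control.rel_tol,
        atol=control.abs_tol,
    )
    if sol.status == -1:
        raise RuntimeError(f"integration failed: {sol.message}")

    times = list(sol.t)
    states = list(sol.y.T)

    event_times: dict[str, float] = {}
    terminated_by: str | None = None
    if events:
        for ev, t_ev, y_ev in zip(events, sol.t_events, sol.y_events):
            if len(t_ev):
                event_times[ev.name] = float(t_ev[0])
        if sol.status == 1:
            # the terminal event is the earliest fired terminal one
            fired = [(event_times[ev.name], ev.name, i)
                     for i, ev in enumerate(events)
                     if ev.terminal and ev.name in event_times]
            fired.sort()
            t_term, terminated_by, idx = fired[0]
            if not times or t_term > times[-1] + 1e-12:
                times.append(t_term)
                states.append(sol.y_events[idx][0])

    times_arr = np.asarray(times)
    states_arr = np.clip(np.asarray(states), -1e-9, None)
    # guard against duplicate terminal time stamps
    keep = np.concatenate(([True], np.diff(times_arr) > 0))
    return Trajectory(
        times=times_arr[keep],
        states=states_arr[keep],
        monitor_index=monitor_index,
        event_times=event_times,
        terminated_by=terminated_by,
    )


def _high_root_guess(r: np.ndarray, p: LocalParams) -> np.ndarray:
    """Vectorized Newton iteration toward the high-biomass root, per site.

    Starts at K; sites whose local parameters have no high root keep K as
    an optimistic guess (the subsequent relaxation decides their fate).
    """
    r = np.asarray(r, dtype=float)
    N = np.full(r.shape, float(p.K))
    for _ in range(80):
        f = r * N * (1.0 - N / p.K) - p.c * N * N / (N * N + p.H * p.H)
        s = N * N + p.H * p.H
        df = r * (1.0 - 2.0 * N / p.K) - 2.0 * p.c * N * p.H * p.H / (s * s)
        step = np.where(np.abs(df) > 1e-12, f / df, 0.0)
        N = np.clip(N - step, 0.0, 1.5 * p.K)
    # reject iterates that escaped the upper branch
    bad = (N < 0.3 * p.K) | ~np.isfinite(N)
    return np.where(bad, float(p.K), N)


def settle_to_equilibrium(
    landscape: Landscape,
    control: IntegrationControl | None = None,
) -> Landscape:
    """Place the landscape on its high-biomass attractor.

    Homogeneous landscapes are set exactly to the upper stable root of the
    local model.  Heterogeneous ones start from per-site root guesses and
    relax by integration until the steady-state criterion is met; if the
    settled state has collapsed (spatial mean below the basin boundary of
    the mean-r local model) no high-biomass attractor exists and
    :class:`NoHighStateError` is raised.
    """
    control = control or IntegrationControl()
    if isinstance(landscape, ContinuousLandscape):
        r = landscape.r_field
    else:
        r = landscape.r_vec
    p = landscape.params

    homogeneous = np.ptp(r) == 0
    if homogeneous:
        eqs = find_equilibria(p.with_r(float(r.flat[0])))
        high = eqs.high_state
        if high is None or high < 1e-6 or (
            eqs.threshold is not None and high <= eqs.threshold
        ):
            raise NoHighStateError(
                f"no high-biomass equilibrium at c={p.c}, r={float(r.flat[0])}"
            )
        if eqs.threshold is None and len(eqs.stable) == 1 and high < 0.3 * p.K:
            raise NoHighStateError(f"only a low state exists at c={p.c}")
        return landscape.with_biomass(np.full_like(landscape.biomass, high, dtype=float))

    guess = _high_root_guess(r, p)
    candidate = landscape.with_biomass(guess)
    traj = integrate(
        candidate,
        control,
        stop_events=[steady_state_event(candidate, control)],
    )
    settled = np.clip(traj.final_state.reshape(landscape.biomass.shape), 0.0, None)
    if traj.terminated_by != "steady_state":
        raise NoHighStateError("landscape failed to settle within t_max")

    mean_r = float(np.mean(r))
    eqs = find_equilibria(p.with_r(mean_r))
    thr = eqs.threshold
    if thr is not None and settled.mean() < thr:
        raise NoHighStateError(
            f"landscape collapsed while settling (c={p.c}, mean r={mean_r:.3f})"
        )
    if settled.mean() < 0.2 * p.K:
        raise NoHighStateError(f"settled state is the overexploited one (c={p.c})")
    return landscape.with_biomass(settled)
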