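"""Harvest-rate sweeps and replicated random-disturbance experiments.

The measurement protocol: for each harvest rate ``c`` on a grid (default
1.8 to 2.8 in steps of 0.05), settle the landscape on its high-biomass
state, apply a pulse disturbance, classify the outcome, and record the
recovery rate (1/recovery time) where recovery occurs.  Standardized
sweeps use one homogeneous landscape and a fixed pulse (center square or
degree-4 focus patch) per c; random sweeps draw a heterogeneous growth
field per replicate and a fresh random pulse per (replicate, c), then
aggregate means, 10th/90th percentiles, outcome fractions, and residuals
of recovery rate after an ordinary least-squares correction for the
pulse covariate (disturbed area A or focus-patch degree k).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from respulse._rng import substream
from respulse.disturbance import (
    DisturbanceSpec,
    Outcome,
    OutcomeClass,
    run_disturbance_experiment,
)
from respulse.dynamics import (
    IntegrationControl,
    NoHighStateError,
    settle_to_equilibrium,
)
from respulse.landscapes import (
    HeterogeneitySpec,
    heterogeneous_r_field,
    make_continuous,
    make_patchy,
    make_random_network,
    patch_growth_rates,
    select_focus_patch,
)
from respulse.local_model import LocalParams, scan_folds

__all__ = [
    "SweepConfig",
    "SweepSummary",
    "default_c_grid",
    "run_standardized_sweep",
    "run_random_sweep",
    "aggregate",
    "covariate_residuals",
    "collapse_boundary",
]

logger = logging.getLogger(__name__)

_RESOLVED = (
    OutcomeClass.RECOVERED.value,
    OutcomeClass.INDUCED_COLLAPSE.value,
    OutcomeClass.NO_RECOVERY.value,
)


def default_c_grid(start: float = 1.8, stop: float = 2.8, step: float = 0.05) -> np.ndarray:
    n = int(round((stop - start) / step))
    return np.round(np.linspace(start, stop, n + 1), 10)


@dataclass(frozen=True)
class SweepConfig:
    """One scenario of the disturbance-recovery measurement campaign."""

    landscape: str                              # "continuous" | "patchy"
    dispersal: float                            # D (m^2/day) or d (1/day)
    disturbance: DisturbanceSpec
    c_grid: tuple[float, ...] = dc_field(
        default_factory=lambda: tuple(default_c_grid())
    )
    replicates: int = 1
    heterogeneity: HeterogeneitySpec | None = None
    params: LocalParams = LocalParams()
    # continuous geometry
    n_x: int = 50
    n_y: int = 50
    cell_size: float = 2.0
    # patchy geometry
    n_patches: int = 100
    edge_probability: float = 0.04
    seed: int = 0
    control: IntegrationControl = IntegrationControl()
    scenario: str = ""
    #: random-square size bounds (area fraction) for the random sweep
    random_size_range: tuple[float, float] = (0.01, 0.05)

    def __post_init__(self) -> None:
        if self.landscape not in ("continuous", "patchy"):
            raise ValueError(f"unknown landscape kind {self.landscape!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        cg = np.asarray(self.c_grid)
        if cg.size == 0 or np.any(np.diff(cg) <= 0):
            raise ValueError("c_grid must be non-empty and ascending")


@dataclass
class SweepSummary:
    """Per-c aggregate statistics of a sweep."""

    table: pd.DataFrame
    residuals: pd.DataFrame | None = None


def _outcome_row(config: SweepConfig, c: float, replicate: int,
                 outcome: Outcome) -> dict:
    return {
        "scenario": config.scenario,
        "landscape": config.landscape,
        "dispersal": config.dispersal,
        "kind": config.disturbance.kind,
        "size": config.disturbance.size,
        "c": c,
        "replicate": replicate,
        "outcome_class": outcome.outcome_class.value,
        "recovery_time": outcome.recovery_time,
        "recovery_rate": outcome.recovery_rate,
        "covariate": outcome.covariate,
        "affected_area": outcome.affected_area,
        "seed": config.seed,
    }


def _beyond_fold_row(config: SweepConfig, c: float, replicate: int) -> dict:
    return _outcome_row(
        config, c, replicate, Outcome(OutcomeClass.BEYOND_FOLD)
    )


def run_standardized_sweep(
    config: SweepConfig,
    network=None,
) -> pd.DataFrame:
    """One standardized pulse per harvest rate on a homogeneous landscape.

    The patchy network (and its degree-4 focus patch) is drawn once per
    sweep so that only c varies along the curve; a pre-built adjacency may
    be passed in to share one network across scenarios.  Harvest rates at
    which the high-biomass state no longer exists are recorded with class
    ``beyond_fold``.
    """
    if config.heterogeneity is not None:
        raise ValueError("standardized sweeps use a homogeneous landscape")
    rows = []
    spec = config.disturbance

    if config.landscape == "patchy":
        if network is None:
            network = make_random_network(
                config.n_patches, config.edge_probability,
                substream(config.seed, "network"),
            )
        focus = select_focus_patch(network, 4, substream(config.seed, "focus"))
        spec = replace(spec, location=focus)
    else:
        spec = replace(spec, location="center")

    for c in config.c_grid:
        params = config.params.with_c(float(c))
        if config.landscape == "continuous":
            base = make_continuous(config.dispersal, params,
                                   config.n_x, config.n_y, config.cell_size)
        else:
            base = make_patchy(config.dispersal, params, network)
        try:
            settled = settle_to_equilibrium(base, config.control)
        except NoHighStateError:
            rows.append(_beyond_fold_row(config, float(c), 0))
            continue
        outcome, _ = run_disturbance_experiment(
            settled, spec, config.control,
            substream(config.seed, "disturbance", 0, int(round(c * 1000))),
        )
        rows.append(_outcome_row(config, float(c), 0, outcome))
        logger.info("standardized %s c=%.3f -> %s", config.scenario, c,
                    rows[-1]["outcome_class"])
    return pd.DataFrame(rows)


def run_random_sweep(
    config: SweepConfig,
    network=None,
) -> pd.DataFrame:
    """Replicated random pulses on heterogeneous landscapes.

    Each replicate is one heterogeneous landscape realization probed with
    one fresh random disturbance per harvest rate: a square of random size
    (area fraction ~ U over ``random_size_range``) at a random position on
    the continuous landscape, or a uniformly random single patch on the
    patchy landscape.
    """
    if config.heterogeneity is None:
        raise ValueError("random sweeps require a heterogeneity spec")
    if config.replicates < 2:
        raise ValueError("random sweeps need at least 2 replicates")
    het = config.heterogeneity
    rows = []

    if config.landscape == "patchy" and network is None:
        network = make_random_network(
            config.n_patches, config.edge_probability,
            substream(config.seed, "network"),
        )

    for rep in range(config.replicates):
        rng_het = substream(config.seed, "heterogeneity", rep)
        if config.landscape == "continuous":
            r_field = heterogeneous_r_field(
                het, config.n_x, config.n_y, config.cell_size, rng_het
            )
        else:
            r_vec = patch_growth_rates(config.n_patches, het.r_low, het.r_high,
                                       rng_het)
        for ic, c in enumerate(config.c_grid):
            params = config.params.with_c(float(c))
            rng_dist = substream(config.seed, "disturbance", rep, ic)
            if config.landscape == "continuous":
                base = make_continuous(config.dispersal, params,
                                       config.n_x, config.n_y,
                                       config.cell_size, r=r_field)
                lo, hi = config.random_size_range
                spec = DisturbanceSpec("square_local",
                                       float(rng_dist.uniform(lo, hi)),
                                       location="random")
            else:
                base = make_patchy(config.dispersal, params, network, r=r_vec)
                spec = DisturbanceSpec("patch_local", 1, location="random")
            try:
                settled = settle_to_equilibrium(base, config.control)
            except NoHighStateError:
                rows.append(_beyond_fold_row(config, float(c), rep))
                continue
            outcome, _ = run_disturbance_experiment(
                settled, spec, config.control, rng_dist
            )
            rows.append(_outcome_row(config, float(c), rep, outcome))
        logger.info("random sweep %s replicate %d/%d done",
                    config.scenario, rep + 1, config.replicates)
    return pd.DataFrame(rows)


def aggregate(outcomes: pd.DataFrame) -> SweepSummary:
    """Per-c summary: recovery-rate mean and 10th/90th percentiles over the
    recovered replicates, plus outcome fractions over resolved runs.

    Percentiles interpolate linearly between order statistics.  Runs
    flagged unresolved or beyond the fold are excluded from fractions.
    """
    recs = []
    for c, grp in outcomes.groupby("c", sort=True):
        resolved = grp[grp["outcome_class"].isin(_RESOLVED)]
        rec = resolved[resolved["outcome_class"] == OutcomeClass.RECOVERED.value]
        n = len(resolved)
        row = {
            "c": c,
            "n_resolved": n,
            "n_recovered": len(rec),
            "recovered_fraction": len(rec) / n if n else np.nan,
            "no_recovery_fraction": (
                (resolved["outcome_class"] == OutcomeClass.NO_RECOVERY.value).sum() / n
                if n else np.nan
            ),
            "induced_collapse_fraction": (
                (resolved["outcome_class"] == OutcomeClass.INDUCED_COLLAPSE.value).sum() / n
                if n else np.nan
            ),
        }
        if len(rec):
            rates = rec["recovery_rate"].to_numpy(dtype=float)
            row.update(
                mean_recovery_rate=float(np.mean(rates)),
                p10_recovery_rate=float(np.percentile(rates, 10)),
                p90_recovery_rate=float(np.percentile(rates, 90)),
            )
        else:
            row.update(mean_recovery_rate=np.nan, p10_recovery_rate=np.nan,
                       p90_recovery_rate=np.nan)
        recs.append(row)
    return SweepSummary(table=pd.DataFrame(recs))


def covariate_residuals(
    outcomes: pd.DataFrame,
    covariate: str = "covariate",
    per_c: bool = True,
    min_points: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OLS correction of recovery rate for the pulse covariate.

    Fits recovery_rate ~ intercept + covariate by least squares over the
    recovered replicates (per c level by default), and returns the table
    of recovered rows with a ``residual`` column plus per-group residual
    statistics (mean, variance, 10th/90th percentiles, raw-rate variance).
    A constant covariate degenerates to deviations from the group mean.
    """
    rec = outcomes[
        outcomes["outcome_class"] == OutcomeClass.RECOVERED.value
    ].copy()
    groups = rec.groupby("c", sort=True) if per_c else [(None, rec)]

    residual = pd.Series(np.nan, index=rec.index)
    stats = []
    for key, grp in groups:
        y = grp["recovery_rate"].to_numpy(dtype=float)
        x = grp[covariate].to_numpy(dtype=float)
        if len(grp) < min_points:
            continue
        if np.ptp(x) == 0:
            logger.warning("constant covariate at c=%s; residuals are "
                           "deviations from the mean", key)
            fitted = np.full_like(y, y.mean())
        else:
            coef = np.polyfit(x, y, 1)
            fitted = np.polyval(coef, x)
        res = y - fitted
        residual.loc[grp.index] = res
        stats.append({
            "c": key,
            "n": len(grp),
            "residual_mean": float(res.mean()),
            "residual_var": float(res.var()),
            "raw_var": float(y.var()),
            "p10_residual": float(np.percentile(res, 10)),
            "p90_residual": float(np.percentile(res, 90)),
        })
    rec["residual"] = residual
    return rec, pd.DataFrame(stats)


def collapse_boundary(
    outcomes: pd.DataFrame,
    params: LocalParams | None = None,
) -> dict:
    """Smallest c whose standardized run did not recover, vs the local fold.

    Returns a dict with ``c_first_nonrecovered`` (None if every c in range
    recovered), the outcome class at that c, and the local-model
    ``c_fold_high`` for comparison.
    """
    params = params or LocalParams()
    _, c_fold_high = scan_folds(params)
    df = outcomes.sort_values("c")
    nonrec = df[df["outcome_class"] != OutcomeClass.RECOVERED.value]
    if nonrec.empty:
        return {"c_first_nonrecovered": None, "boundary_class": None,
                "c_fold_high": c_fold_high}
    first = nonrec.iloc[0]
    return {
        "c_first_nonrecovered": float(first["c"]),
        "boundary_class": first["outcome_class"],
        "c_fold_high": c_fold_high,
    }
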