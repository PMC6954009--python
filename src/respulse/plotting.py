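"""Minimal plotting helpers (diagnostics, not publication figures)."""

from __future__ import annotations

def plot_sweep_summary(summary_table, ax=None):
    """Mean recovery rate vs harvest rate with the 10th-90th percentile band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = summary_table
    ax.fill_between(t["c"], t["p10_recovery_rate"], t["p90_recovery_rate"],
                    alpha=0.3, color="grey", label="10th-90th pct")
    ax.plot(t["c"], t["mean_recovery_rate"], color="black", label="mean")
    if "no_recovery_fraction" in t:
        ax2 = ax.twinx()
        ax2.plot(t["c"], t["no_recovery_fraction"], color="green",
                 label="no-recovery fraction")
        ax2.set_ylabel("no-recovery fraction")
        ax2.set_ylim(0, 1)
    ax.set_xlabel("harvest rate c (g m$^{-2}$ day$^{-1}$)")
    ax.set_ylabel("recovery rate (day$^{-1}$)")
    return ax


def plot_trajectory(trajectory, ax=None):
    """Monitored-site and spatial-mean biomass over time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(trajectory.times, trajectory.monitored_site_series,
            label="monitored site")
    ax.plot(trajectory.times, trajectory.spatial_mean_series,
            label="spatial mean", linestyle="--")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("biomass (g m$^{-2}$)")
    ax.legend()
    return ax
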