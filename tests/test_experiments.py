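"""Sweep orchestration and aggregation statistics."""

import numpy as np
import pandas as pd
import pytest

from respulse import (
    DisturbanceSpec,
    HeterogeneitySpec,
    LocalParams,
    SweepConfig,
    aggregate,
    collapse_boundary,
    covariate_residuals,
    default_c_grid,
    run_random_sweep,
    run_standardized_sweep,
)


def _outcome_frame(rates, covariates=None, c=2.0, classes=None):
    n = len(rates)
    classes = classes or ["recovered"] * n
    return pd.DataFrame({
        "c": [c] * n,
        "replicate": range(n),
        "outcome_class": classes,
        "recovery_rate": rates,
        "covariate": covariates if covariates is not None else [1.0] * n,
    })


class TestAggregate:
    def test_percentiles_linear_interpolation(self):
        # rates 1..10: mean 5.5, 10th pct 1.9, 90th pct 9.1 under the
        # linear order-statistic interpolation convention
        df = _outcome_frame(list(range(1, 11)))
        row = aggregate(df).table.iloc[0]
        assert row["mean_recovery_rate"] == pytest.approx(5.5)
        assert row["p10_recovery_rate"] == pytest.approx(1.9)
        assert row["p90_recovery_rate"] == pytest.approx(9.1)

    def test_single_recovered_replicate(self):
        df = _outcome_frame([0.25])
        row = aggregate(df).table.iloc[0]
        assert row["mean_recovery_rate"] == 0.25
        assert row["p10_recovery_rate"] == 0.25
        assert row["p90_recovery_rate"] == 0.25

    def test_all_no_recovery(self):
        df = _outcome_frame([None] * 4, classes=["no_recovery"] * 4)
        row = aggregate(df).table.iloc[0]
        assert row["no_recovery_fraction"] == 1.0
        assert np.isnan(row["mean_recovery_rate"])

    def test_fractions_exclude_unresolved_and_beyond_fold(self):
        df = _outcome_frame(
            [0.2, 0.1, None, None],
            classes=["recovered", "recovered", "unresolved", "beyond_fold"],
        )
        row = aggregate(df).table.iloc[0]
        assert row["n_resolved"] == 2
        assert row["recovered_fraction"] == 1.0


class TestCovariateResiduals:
    def test_perfectly_linear_rates_leave_zero_residuals(self):
        A = np.array([100.0, 200, 300, 400, 500])
        rates = 0.5 - 0.0005 * A
        df = _outcome_frame(rates, covariates=A)
        rec, stats = covariate_residuals(df)
        assert np.allclose(rec["residual"], 0.0, atol=1e-12)
        assert stats.iloc[0]["residual_var"] == pytest.approx(0.0, abs=1e-20)

    def test_residual_mean_zero_per_c(self, rng):
        frames = []
        for c in (2.0, 2.2):
            A = rng.uniform(100, 500, 12)
            rates = 0.3 - 0.0003 * A + rng.normal(0, 0.01, 12)
            frames.append(_outcome_frame(rates, covariates=A, c=c))
        rec, stats = covariate_residuals(pd.concat(frames, ignore_index=True))
        for _, row in stats.iterrows():
            assert row["residual_mean"] == pytest.approx(0.0, abs=1e-12)
            assert row["residual_var"] <= row["raw_var"] + 1e-15

    def test_constant_covariate_degenerates_to_mean_deviation(self):
        rates = [0.1, 0.2, 0.3]
        df = _outcome_frame(rates, covariates=[4.0, 4.0, 4.0])
        rec, _ = covariate_residuals(df)
        assert np.allclose(rec["residual"], np.array(rates) - 0.2)

    def test_too_few_points_skipped(self):
        df = _outcome_frame([0.1, 0.2], covariates=[1.0, 2.0])
        rec, stats = covariate_residuals(df)
        assert stats.empty
        assert rec["residual"].isna().all()


@pytest.fixture(scope="module")
def standardized(request):
    cfg = SweepConfig(
        landscape="continuous", dispersal=12.5,
        disturbance=DisturbanceSpec("square_local", 0.01),
        c_grid=tuple(default_c_grid(2.0, 2.6, 0.2)),
        n_x=20, n_y=20, cell_size=5.0, seed=3, scenario="unit",
    )
    return cfg, run_standardized_sweep(cfg)


@pytest.fixture(scope="module")
def random_sweep_fixture():
    cfg = SweepConfig(
        landscape="patchy", dispersal=0.02,
        disturbance=DisturbanceSpec("patch_local", 1, location="random"),
        c_grid=(2.0, 2.2), replicates=4,
        heterogeneity=HeterogeneitySpec(),
        n_patches=30, edge_probability=0.14, seed=5, scenario="unit-random",
    )
    return cfg, run_random_sweep(cfg)


class TestStandardizedSweep:
    @pytest.fixture
    def sweep(self, standardized):
        return standardized

    def test_one_row_per_c(self, sweep):
        cfg, df = sweep
        assert len(df) == len(cfg.c_grid)

    def test_recovery_rate_declines_with_c(self, sweep):
        _, df = sweep
        rates = df[df.outcome_class == "recovered"].recovery_rate.to_numpy()
        assert len(rates) >= 3
        assert np.all(np.diff(rates) < 0)

    def test_reproducible(self, sweep):
        cfg, df = sweep
        again = run_standardized_sweep(cfg)
        pd.testing.assert_frame_equal(df, again)

    def test_collapse_boundary_never_exceeds_fold(self, sweep):
        _, df = sweep
        info = collapse_boundary(df)
        if info["c_first_nonrecovered"] is not None:
            assert info["c_first_nonrecovered"] <= info["c_fold_high"] + 1e-9


class TestRandomSweep:
    @pytest.fixture
    def sweep(self, random_sweep_fixture):
        return random_sweep_fixture

    def test_row_count(self, sweep):
        cfg, df = sweep
        assert len(df) == cfg.replicates * len(cfg.c_grid)

    def test_covariate_is_degree(self, sweep):
        _, df = sweep
        recovered = df[df.outcome_class == "recovered"]
        assert (recovered["covariate"] >= 0).all()
        assert (recovered["covariate"] == recovered["covariate"].round()).all()

    def test_requires_heterogeneity_and_replicates(self):
        cfg = SweepConfig(
            landscape="patchy", dispersal=0.02,
            disturbance=DisturbanceSpec("patch_local", 1),
            n_patches=30, replicates=1, heterogeneity=HeterogeneitySpec(),
        )
        with pytest.raises(ValueError):
            run_random_sweep(cfg)

    def test_different_seed_changes_draws(self, sweep):
        from dataclasses import replace

        cfg, df = sweep
        other = run_random_sweep(replace(cfg, seed=6))
        assert not df["covariate"].equals(other["covariate"]) or \
            not df["recovery_rate"].equals(other["recovery_rate"])


class TestRandomDisturbanceDistributions:
    def test_square_sizes_match_uniform_draws(self, rng):
        # covariate A across random draws reflects size ~ U[0.01, 0.05]
        # of the 1e4 m^2 domain (rasterized to whole cells)
        from respulse.disturbance import apply_disturbance
        from respulse.dynamics import settle_to_equilibrium
        from respulse import make_continuous

        settled = settle_to_equilibrium(make_continuous(2.5, LocalParams(c=2.0)))
        areas = []
        for _ in range(300):
            size = rng.uniform(0.01, 0.05)
            applied = apply_disturbance(
                settled, DisturbanceSpec("square_local", size, "random"), rng
            )
            areas.append(applied.covariate)
        areas = np.array(areas)
        assert areas.min() >= 50.0 and areas.max() <= 600.0
        assert areas.mean() == pytest.approx(300.0, rel=0.15)

    def test_random_patch_uniform_over_network(self, rng):
        from respulse.disturbance import apply_disturbance
        from respulse.dynamics import settle_to_equilibrium
        from respulse import make_patchy, make_random_network
        from scipy.stats import chisquare

        net = make_random_network(25, 0.2, rng=0)
        settled = settle_to_equilibrium(make_patchy(0.02, LocalParams(c=2.0), net))
        counts = np.zeros(25)
        for _ in range(2500):
            applied = apply_disturbance(
                settled, DisturbanceSpec("patch_local", 1, "random"), rng
            )
            counts[int(np.flatnonzero(applied.footprint)[0])] += 1
        assert chisquare(counts).pvalue > 0.001
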