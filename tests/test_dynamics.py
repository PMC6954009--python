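"""Time integration: diffusion stencil, right-hand sides, events, settling."""

import numpy as np
import pytest
import scipy.sparse as sp

from respulse import (
    IntegrationControl,
    LocalParams,
    make_continuous,
    make_patchy,
    make_random_network,
)
from respulse.dynamics import (
    NoHighStateError,
    continuous_rhs,
    integrate,
    laplacian_term,
    patchy_rhs,
    settle_to_equilibrium,
    steady_state_event,
)
from respulse.local_model import find_equilibria, growth_rate


class TestLaplacian:
    def test_uniform_field_is_flat(self):
        assert np.all(laplacian_term(np.full((6, 7), 3.2), 2.0, 2.5) == 0)

    def test_zero_flux_conserves_mass(self, rng):
        field = rng.uniform(0, 10, size=(9, 11))
        lap = laplacian_term(field, 2.0, 2.5)
        assert lap.sum() == pytest.approx(0.0, abs=1e-10)

    def test_interior_spike_stencil(self):
        # D/h^2 = 1: the stencil gives -4 at the spike and +1 at its four
        # von Neumann neighbours
        field = np.zeros((7, 7))
        field[3, 3] = 1.0
        lap = laplacian_term(field, cell_size=2.0, D=4.0)
        assert lap[3, 3] == -4.0
        for i, j in [(2, 3), (4, 3), (3, 2), (3, 4)]:
            assert lap[i, j] == 1.0
        assert lap.sum() == pytest.approx(0.0, abs=1e-12)


class TestContinuousRHS:
    def test_equilibrium_field_is_stationary(self, default_params):
        high = find_equilibria(default_params).high_state
        L = make_continuous(2.5, default_params, n_x=10, n_y=10, cell_size=10.0)
        L = L.with_biomass(np.full((10, 10), high))
        assert np.max(np.abs(continuous_rhs(L))) < 1e-9

    def test_no_diffusion_reduces_to_local_model(self, default_params, rng):
        field = rng.uniform(0, 10, size=(5, 5))
        L = make_continuous(0.0, default_params, n_x=5, n_y=5, cell_size=2.0)
        L = L.with_biomass(field)
        assert np.allclose(continuous_rhs(L), growth_rate(field, default_params))

    def test_matches_naive_double_loop(self, default_params, rng):
        field = rng.uniform(0, 10, size=(5, 5))
        r_field = rng.uniform(0.8, 1.2, size=(5, 5))
        L = make_continuous(2.5, default_params, n_x=5, n_y=5, cell_size=2.0,
                            r=r_field)
        L = L.with_biomass(field)
        out = continuous_rhs(L)

        expected = np.empty_like(field)
        n_y, n_x = field.shape
        for i in range(n_y):
            for j in range(n_x):
                N = field[i, j]
                p = default_params
                f = (r_field[i, j] * N * (1 - N / p.K)
                     - p.c * N**2 / (N**2 + p.H**2))
                nb = 0.0
                for di, dj in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
                    ii = min(max(i + di, 0), n_y - 1)
                    jj = min(max(j + dj, 0), n_x - 1)
                    nb += field[ii, jj] - N
                expected[i, j] = f + 2.5 / 4.0 * nb
        assert np.allclose(out, expected, atol=1e-12)


class TestPatchyRHS:
    def _landscape(self, d, default_params, n=20, seed=0):
        net = make_random_network(n, 0.2, rng=seed)
        return make_patchy(d, default_params, net)

    def test_symmetric_state_no_net_coupling(self, default_params):
        L = self._landscape(0.05, default_params)
        L = L.with_biomass(np.full(L.n_patches, 4.0))
        expected = growth_rate(4.0, default_params)
        assert np.allclose(patchy_rhs(L), expected)

    def test_zero_dispersal_decouples(self, default_params, rng):
        L = self._landscape(0.0, default_params)
        state = rng.uniform(0, 10, L.n_patches)
        L = L.with_biomass(state)
        assert np.allclose(patchy_rhs(L), growth_rate(state, default_params))

    def test_coupling_conserves_biomass(self, default_params, rng):
        L = self._landscape(0.07, default_params)
        state = rng.uniform(0, 10, L.n_patches)
        coupling = patchy_rhs(L.with_biomass(state)) - growth_rate(state, default_params)
        assert coupling.sum() == pytest.approx(0.0, abs=1e-10)


class TestIntegrate:
    def test_equilibrium_is_invariant(self, default_params):
        L = settle_to_equilibrium(
            make_continuous(2.5, default_params, n_x=10, n_y=10, cell_size=10.0)
        )
        control = IntegrationControl(t_max=100.0)
        traj = integrate(L, control)
        assert np.ptp(traj.monitored_site_series) < 1e-6

    def test_pure_diffusion_conserves_total_biomass(self, rng):
        # growth switched off (r negligible, c = 0): diffusion alone must
        # conserve biomass on the closed domain to solver tolerance
        p = LocalParams(r=1e-12, c=0.0)
        L = make_continuous(5.0, p, n_x=12, n_y=12, cell_size=2.0)
        L = L.with_biomass(rng.uniform(0, 10, size=(12, 12)))
        traj = integrate(L, IntegrationControl(t_max=20.0))
        totals = traj.states.sum(axis=1)
        assert np.max(np.abs(totals - totals[0])) / totals[0] < 1e-7

    def test_high_dispersal_patchy_matches_well_mixed(self, default_params):
        # strongly coupled patches homogenize: the spatial mean follows the
        # single-compartment local model within 1%
        from scipy.integrate import solve_ivp

        net = make_random_network(30, 0.3, rng=4)
        L = make_patchy(10.0, default_params, net)
        y0 = np.full(30, 5.0)
        L = L.with_biomass(y0)
        traj = integrate(L, IntegrationControl(t_max=20.0))

        sol = solve_ivp(
            lambda t, y: [growth_rate(max(y[0], 0.0), default_params)],
            (0, 20.0), [5.0], rtol=1e-10, atol=1e-12, t_eval=traj.times,
        )
        mean = traj.spatial_mean_series
        assert np.max(np.abs(mean - sol.y[0])) / np.max(sol.y[0]) < 0.01

    def test_non_negative_along_trajectory(self, default_params):
        L = settle_to_equilibrium(
            make_continuous(2.5, default_params, n_x=10, n_y=10, cell_size=10.0)
        )
        biomass = L.biomass.copy()
        biomass[3:6, 3:6] = 0.0
        traj = integrate(L.with_biomass(biomass), IntegrationControl(t_max=50.0))
        assert traj.states.min() >= -1e-9

    def test_long_format_export(self, default_params):
        L = settle_to_equilibrium(
            make_continuous(2.5, default_params, n_x=4, n_y=3, cell_size=10.0)
        )
        traj = integrate(L, IntegrationControl(t_max=3.0))
        frame = traj.to_long_frame()
        assert list(frame.columns) == ["time", "site", "biomass"]
        assert len(frame) == len(traj.times) * 12
        wide = frame.pivot(index="time", columns="site", values="biomass")
        assert np.allclose(wide.to_numpy(), traj.states)

    def test_steady_state_event_fires(self, default_params):
        L = make_continuous(2.5, default_params, n_x=10, n_y=10, cell_size=10.0)
        L = L.with_biomass(np.full((10, 10), 5.0))
        control = IntegrationControl()
        traj = integrate(L, control, stop_events=[steady_state_event(L, control)])
        assert traj.terminated_by == "steady_state"
        assert traj.t_final < control.t_max


class TestSettle:
    def test_homogeneous_exact_root(self, default_params):
        L = settle_to_equilibrium(make_continuous(2.5, default_params))
        high = find_equilibria(default_params).high_state
        assert np.allclose(L.biomass, high)
        assert np.max(np.abs(continuous_rhs(L))) < 1e-6

    def test_heterogeneous_residual_below_epsilon(self, default_params):
        from respulse.landscapes import HeterogeneitySpec, heterogeneous_r_field

        r = heterogeneous_r_field(HeterogeneitySpec(), n_x=20, n_y=20,
                                  cell_size=5.0, rng=8)
        L = make_continuous(2.5, default_params, n_x=20, n_y=20, cell_size=5.0, r=r)
        settled = settle_to_equilibrium(L)
        # the steady-state event fires exactly at the epsilon crossing
        assert np.max(np.abs(continuous_rhs(settled))) <= 1e-6 * (1 + 1e-6)
        # richer cells hold weakly more biomass
        flat_r, flat_n = r.ravel(), settled.biomass.ravel()
        assert np.corrcoef(flat_r, flat_n)[0, 1] > 0.5

    def test_no_high_state_raises(self):
        with pytest.raises(NoHighStateError):
            settle_to_equilibrium(make_continuous(2.5, LocalParams(c=3.0)))
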