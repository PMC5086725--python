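"""Model dynamics: initial conditions, RHS, integrator, aggregation."""

import numpy as np
import pytest

from evacsi import (
    CommunityLayout,
    EvacuationState,
    ModelParameters,
    WarningSchedule,
    aggregate,
    closed_form_logistic,
    initial_state,
    integrate,
    rhs,
    tianjin_like_scenario,
    two_community_fixture,
)


def max_rel_logistic_error(layout, params, init, dt, horizon=50.0):
    traj = integrate(layout, params, init, dt=dt, horizon=horizon)
    rate = params.gamma[0] * params.kernel.lambda0
    exact = closed_form_logistic(traj.times, 100.0, 20.0, rate)
    return float(np.max(np.abs(traj.I[:, 0, 0] - exact) / exact))


class TestInitialState:
    def layout(self, dists=(1.0, 2.0)):
        n = len(dists)
        pw = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        return CommunityLayout(
            dist_to_source=np.array(dists),
            pairwise=pw,
            populations=np.full((3, n), 500.0),
        )

    def test_anchor_identity(self, table1):
        st = initial_state(self.layout(), table1, (0, 0, 150.0))
        assert st.I[0, 0] == pytest.approx(150.0)

    def test_gamma_ratio_scaling(self, table1):
        # gamma3/gamma1 = 0.2/0.5 scales the anchor community's type-3 count
        st = initial_state(self.layout(), table1, (0, 0, 150.0))
        assert st.I[2, 0] == pytest.approx(60.0)

    def test_inverse_cube_distance_scaling(self, table1):
        st = initial_state(self.layout(dists=(1.0, 2.0)), table1, (0, 0, 150.0))
        assert st.I[0, 1] == pytest.approx(150.0 / 8)

    @pytest.mark.parametrize("power,expected", [(1, 75.0), (2, 37.5), (3, 18.75)])
    def test_configurable_distance_power(self, table1, power, expected):
        st = initial_state(self.layout(), table1, (0, 0, 150.0), power=power)
        assert st.I[0, 1] == pytest.approx(expected)

    def test_anchor_exceeding_population_rejected(self, table1):
        with pytest.raises(ValueError, match="exceeds"):
            initial_state(self.layout(), table1, (0, 0, 600.0))

    def test_clamped_to_population(self, table1):
        # a very close non-anchor community would overshoot its group size
        lay = self.layout(dists=(5.0, 0.1))
        st = initial_state(lay, table1, (0, 0, 400.0))
        assert np.all(st.I <= lay.populations + 1e-12)


class TestRHS:
    def test_hand_oracle_within_community_term(
        self, single_group_layout, single_group_state, no_forcing_params
    ):
        # gamma*lambda0*(S/Q)*I = 0.5*0.25*(80/100)*20 = 2.0
        dI = rhs(single_group_state, single_group_layout, no_forcing_params)
        assert dI[0, 0] == pytest.approx(2.0)
        assert np.all(dI[1:] == 0.0)

    def test_no_infectives_no_forcing_is_static(
        self, single_group_layout, no_forcing_params
    ):
        st = EvacuationState(0.0, np.zeros((3, 1)))
        assert np.all(rhs(st, single_group_layout, no_forcing_params) == 0.0)

    def test_saturation_annihilates_all_terms(self, single_group_layout, table1):
        st = EvacuationState(0.0, single_group_layout.populations.copy())
        assert np.all(rhs(st, single_group_layout, table1) == 0.0)

    def test_rates_non_negative(self, table1):
        layout, params, anchor = tianjin_like_scenario(seed=11)
        st = initial_state(layout, params, anchor)
        assert np.all(rhs(st, layout, params) >= 0.0)

    def test_dimension_mismatch_rejected(self, single_group_layout, table1):
        st = EvacuationState(0.0, np.zeros((3, 2)))
        with pytest.raises(ValueError, match="match"):
            rhs(st, single_group_layout, table1)


class TestIntegrate:
    def test_zero_field_constant_trajectory(self, single_group_layout):
        from evacsi import KernelParams, LocationParams

        params = ModelParameters(
            gamma=(0.5, 0.3, 0.2),
            kernel=KernelParams(0.0, 0.0, 1.0),
            location=LocationParams(a2=0.0),
        )
        st = EvacuationState(0.0, np.array([[20.0], [0.0], [0.0]]))
        traj = integrate(single_group_layout, params, st, dt=1.0, horizon=10.0)
        assert np.all(traj.I == st.I)

    def test_logistic_limit_oracle(
        self, single_group_layout, single_group_state, no_forcing_params
    ):
        err = max_rel_logistic_error(
            single_group_layout, no_forcing_params, single_group_state, dt=0.01
        )
        assert err < 1e-2

    def test_first_order_euler_convergence(
        self, single_group_layout, single_group_state, no_forcing_params
    ):
        errs = [
            max_rel_logistic_error(
                single_group_layout, no_forcing_params, single_group_state, dt=dt
            )
            for dt in (0.04, 0.02, 0.01)
        ]
        ratios = [a / b for a, b in zip(errs, errs[1:])]
        assert all(1.7 < r < 2.3 for r in ratios)

    def test_breakpoint_off_grid_rejected(self, single_group_layout, single_group_state):
        params = ModelParameters(
            warning=WarningSchedule(breakpoints=(0.0, 7.5), pieces=((0.01, 0.001), (0.2, 0.01)))
        )
        with pytest.raises(ValueError, match="dt"):
            integrate(single_group_layout, params, single_group_state, dt=2.0, horizon=20.0)

    def test_warning_jump_raises_hourly_increment(self):
        layout, params, anchor = tianjin_like_scenario(seed=2)
        init = initial_state(layout, params, anchor)
        curves = aggregate(integrate(layout, params, init, dt=1.0, horizon=120.0))
        inc = curves.hourly_increments  # inc[i] covers hour (i, i+1]
        assert inc[60] > inc[59]

    def test_no_clamping_before_saturation_at_hourly_step(self):
        # with the case parameters at dt = 1 the Euler step never overshoots:
        # re-integrating without the clamp gives the same trajectory
        layout, params, anchor = tianjin_like_scenario(seed=4)
        init = initial_state(layout, params, anchor)
        traj = integrate(layout, params, init, dt=1.0, horizon=120.0)
        from evacsi.model import _rhs_array, coupling_matrix

        K = coupling_matrix(layout, params.kernel, params.location)
        I = init.I.copy()
        for step in range(120):
            I = I + 1.0 * _rhs_array(step * 1.0, I, layout, params, K)
            assert np.all(I <= layout.populations + 1e-9)
        assert np.allclose(I, traj.I[-1])


class TestConservationMonotonicity:
    @pytest.mark.parametrize("seed", range(10))
    def test_seeded_scenarios_conserve_and_grow(self, seed):
        from evacsi import ScenarioSpec, synthetic_layout, params_table1

        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 62))
        spec = ScenarioSpec(
            n=n,
            total_population=float(rng.uniform(1e3, 2e5)),
            seed=seed,
            equal_populations=bool(rng.integers(0, 2)),
        )
        layout = synthetic_layout(spec)
        params = params_table1()
        init = initial_state(layout, params, (0, 0, min(50.0, layout.populations[0, 0])))
        traj = integrate(layout, params, init, dt=1.0, horizon=120.0)
        # conservation is structural: S = Q - I by construction, I in [0, Q]
        assert np.all(traj.I >= 0.0)
        assert np.all(traj.I <= layout.populations[None] + 1e-12)
        assert np.all(np.diff(traj.I, axis=0) >= -1e-12)


class TestPermutationEquivariance:
    def test_relabeling_permutes_rows_total_invariant(self):
        layout, params, anchor = tianjin_like_scenario(seed=3)
        init = initial_state(layout, params, anchor)
        traj = integrate(layout, params, init, dt=1.0, horizon=40.0)
        perm = np.random.default_rng(0).permutation(layout.n)
        lay_p = CommunityLayout(
            layout.dist_to_source[perm],
            layout.pairwise[np.ix_(perm, perm)],
            layout.populations[:, perm],
        )
        traj_p = integrate(
            lay_p, params, EvacuationState(0.0, init.I[:, perm]), dt=1.0, horizon=40.0
        )
        assert np.allclose(traj_p.I, traj.I[:, :, perm])
        assert np.allclose(aggregate(traj_p).total, aggregate(traj).total)


class TestClosedFormLogistic:
    def test_boundary_behaviour(self):
        assert closed_form_logistic(0.0, 100.0, 20.0, 0.3) == pytest.approx(20.0)
        assert closed_form_logistic(1e6, 100.0, 20.0, 0.3) == pytest.approx(100.0)
        assert closed_form_logistic(50.0, 100.0, 20.0, 0.0) == pytest.approx(20.0)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            closed_form_logistic(1.0, 100.0, 0.0, 0.3)
        with pytest.raises(ValueError):
            closed_form_logistic(1.0, 100.0, 150.0, 0.3)


class TestAggregate:
    def test_regrouped_sums_identical(self):
        layout, params, anchor = tianjin_like_scenario(seed=7)
        init = initial_state(layout, params, anchor)
        curves = aggregate(integrate(layout, params, init, dt=1.0, horizon=60.0))
        np.testing.assert_allclose(curves.by_community.sum(axis=1), curves.total)
        np.testing.assert_allclose(curves.by_type.sum(axis=1), curves.total)

    def test_increments_telescope(self):
        layout, params, anchor = tianjin_like_scenario(seed=7)
        init = initial_state(layout, params, anchor)
        curves = aggregate(integrate(layout, params, init, dt=1.0, horizon=60.0))
        assert curves.hourly_increments.sum() == pytest.approx(
            curves.total[-1] - curves.total[0]
        )

    def test_type_fraction_ordering(self):
        layout, params, anchor = tianjin_like_scenario(seed=7)
        init = initial_state(layout, params, anchor)
        curves = aggregate(integrate(layout, params, init, dt=1.0, horizon=120.0))
        ft = curves.frac_by_type
        assert np.all(ft[:, 0] >= ft[:, 1] - 1e-12)
        assert np.all(ft[:, 1] >= ft[:, 2] - 1e-12)

    def test_constant_trajectory_zero_increments(
        self, single_group_layout, single_group_state
    ):
        from evacsi import KernelParams, LocationParams

        params = ModelParameters(
            kernel=KernelParams(0.0, 0.0, 1.0), location=LocationParams(a2=0.0)
        )
        curves = aggregate(
            integrate(single_group_layout, params, single_group_state, dt=1.0, horizon=10.0)
        )
        assert np.all(curves.hourly_increments == 0.0)


class TestIsolation:
    def test_distant_community_trails_connected_peers(self, table1):
        # identical communities at equal source distance; one moved far away
        from scipy.spatial.distance import pdist, squareform

        angles = np.array([0.0, 0.1, 0.2, 0.3, np.pi])
        d0 = np.full(5, 3.0)
        xy = np.column_stack([d0 * np.cos(angles), d0 * np.sin(angles)])
        layout = CommunityLayout(d0, squareform(pdist(xy)), np.full((3, 5), 200.0))
        init = initial_state(layout, table1, (0, 0, 50.0))
        curves = aggregate(integrate(layout, table1, init, dt=1.0, horizon=120.0))
        fc = curves.frac_by_community
        for connected in (1, 2, 3):
            assert np.all(fc[:, 4] <= fc[:, connected] + 1e-12)


class TestTwoCommunityFixture:
    def test_symmetric_initialisation_stays_symmetric(self, table1):
        layout = two_community_fixture(1.0)
        init = EvacuationState(0.0, np.full((3, 2), 10.0))
        traj = integrate(layout, table1, init, dt=0.5, horizon=40.0)
        np.testing.assert_allclose(traj.I[:, :, 0], traj.I[:, :, 1])

    def test_closer_coupling_accelerates_demand(self, table1):
        def run(d):
            layout = two_community_fixture(d)
            init = initial_state(layout, table1, (0, 0, 30.0))
            return aggregate(integrate(layout, table1, init, dt=0.5, horizon=60.0))

        near, far = run(0.5), run(8.0)
        assert np.all(near.frac_total[1:] >= far.frac_total[1:])
        assert near.frac_total[-1] > far.frac_total[-1]
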