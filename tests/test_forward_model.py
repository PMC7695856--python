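"""Forward model: compartment ODE closed form and spoiled-GRE synthesis."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from placentadce import (
    AcquisitionProtocol,
    AggregationSchedule,
    KineticParams,
    Relaxivity,
    VoxelModel,
    relaxation_rates,
    simulate_voxel,
    solve_compartments,
    spgr_signal,
)


def integrate_reference(kp, t_eval, rtol=1e-11):
    """Independent numerical oracle for the exchange ODE system."""

    def rhs(_, y):
        c2, c3 = y
        return [
            kp.k12 * (kp.c1 - c2) - kp.k23 * (c2 - c3),
            kp.k23 * (c2 - c3),
        ]

    sol = solve_ivp(
        rhs, (0.0, float(t_eval[-1])), [kp.c2_0, kp.c3_0],
        t_eval=t_eval, rtol=rtol, atol=1e-14, method="RK45",
    )
    return sol.y[0], sol.y[1]


class TestSolveCompartments:
    def test_no_exchange_stays_zero(self):
        kp = KineticParams(k12=0.0, k23=0.0, c1=0.2)
        cc = solve_compartments(kp, [0.0, 10.0, 100.0])
        assert np.all(cc.c2 == 0.0)
        assert np.all(cc.c3 == 0.0)

    def test_equilibrium_is_fixed_point(self):
        kp = KineticParams(k12=0.03, k23=0.07, c1=0.104, c2_0=0.104, c3_0=0.104)
        cc = solve_compartments(kp, np.linspace(0, 3000, 25))
        np.testing.assert_allclose(cc.c2, 0.104, rtol=1e-12)
        np.testing.assert_allclose(cc.c3, 0.104, rtol=1e-12)

    def test_matches_numerical_integrator_at_reported_rates(self):
        kp = KineticParams(k12=0.045, k23=0.059, c1=0.104)
        t = np.array([180.0])
        cc = solve_compartments(kp, t)
        c2_ref, c3_ref = integrate_reference(kp, t)
        assert abs(cc.c2[0] - c2_ref[0]) / c2_ref[0] < 1e-6
        assert abs(cc.c3[0] - c3_ref[0]) / c3_ref[0] < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_numerical_integrator_random_rates(self, seed):
        rng = np.random.default_rng(seed)
        kp = KineticParams(
            k12=float(rng.uniform(0.003, 0.3)),
            k23=float(rng.uniform(0.003, 0.3)),
            c1=float(rng.uniform(0.05, 0.5)),
        )
        t = np.linspace(60.0, 3240.0, 12)
        cc = solve_compartments(kp, t)
        c2_ref, c3_ref = integrate_reference(kp, t)
        np.testing.assert_allclose(cc.c2, c2_ref, rtol=1e-6)
        np.testing.assert_allclose(cc.c3, c3_ref, rtol=1e-6)

    def test_degenerate_single_rate_branches(self):
        # k23 = 0: C3 frozen, C2 relaxes exponentially toward c1
        kp = KineticParams(k12=0.02, k23=0.0, c1=0.1, c3_0=0.03)
        t = np.array([0.0, 50.0, 500.0])
        cc = solve_compartments(kp, t)
        np.testing.assert_allclose(cc.c3, 0.03, rtol=1e-12)
        np.testing.assert_allclose(cc.c2, 0.1 * (1 - np.exp(-0.02 * t)), rtol=1e-12)
        # k12 = 0: conserved sum, exponential equilibration of the difference
        kp = KineticParams(k12=0.0, k23=0.05, c1=0.1, c2_0=0.08)
        cc = solve_compartments(kp, t)
        np.testing.assert_allclose(cc.c2 + cc.c3, 0.08, rtol=1e-12)
        # atol floor: the difference underflows double cancellation at late t
        np.testing.assert_allclose(
            cc.c2 - cc.c3, 0.08 * np.exp(-0.1 * t), rtol=1e-12, atol=1e-16
        )

    def test_ordering_invariant_zero_initials(self):
        rng = np.random.default_rng(42)
        t = np.linspace(1.0, 3240.0, 40)
        for _ in range(50):
            kp = KineticParams(
                k12=float(rng.uniform(0.002, 0.3)),
                k23=float(rng.uniform(0.002, 0.3)),
                c1=0.104,
            )
            cc = solve_compartments(kp, t)
            assert np.all(cc.c3 > 0)
            assert np.all(cc.c3 <= cc.c2 + 1e-12)
            assert np.all(cc.c2 <= kp.c1 + 1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(k12=-0.1, k23=0.1), dict(k12=0.1, k23=-0.1), dict(k12=0.1, k23=0.1, c1=-1.0)],
    )
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            KineticParams(**kwargs)

    def test_invalid_times_raise(self):
        kp = KineticParams(k12=0.1, k23=0.1)
        with pytest.raises(ValueError):
            solve_compartments(kp, [-1.0, 2.0])
        with pytest.raises(ValueError):
            solve_compartments(kp, [2.0, 1.0])


class TestRelaxationRates:
    @pytest.mark.parametrize(
        "c, expected", [(1.0, (120.0, 17.0)), (0.0, (0.0, 0.0)), (0.104, (12.48, 1.768))]
    )
    def test_linear_in_concentration(self, c, expected, relaxivity):
        r1, r2 = relaxation_rates(c, relaxivity)
        assert r1 == pytest.approx(expected[0], rel=1e-12)
        assert r2 == pytest.approx(expected[1], rel=1e-12)

    def test_negative_concentration_raises(self, relaxivity):
        with pytest.raises(ValueError):
            relaxation_rates(-0.1, relaxivity)


class TestSpgrSignal:
    def test_saturation_limit(self, protocol):
        p = AcquisitionProtocol(tr=protocol.tr, te=0.0, flip_angle=protocol.flip_angle)
        s = spgr_signal(1e9, 0.0, p, m0=2.5)
        assert s == pytest.approx(2.5 * np.sin(p.flip_angle), rel=1e-9)

    def test_against_independent_closed_form(self):
        # independently coded evaluation of the steady-state expression
        tr, te, theta, r1, r2s, m0 = 0.01, 0.003, np.deg2rad(15.0), 12.48, 60.0, 1.0
        expected = (
            m0 * np.sin(theta) * (1 - np.exp(-tr * r1))
            / (1 - np.cos(theta) * np.exp(-tr * r1))
        ) * np.exp(-te * r2s)
        p = AcquisitionProtocol(tr=tr, te=te, flip_angle=theta)
        assert spgr_signal(r1, r2s, p) == pytest.approx(expected, rel=1e-12)

    def test_monotonicity_and_bounds(self, protocol):
        r1_grid = np.linspace(0.1, 200.0, 80)
        s = spgr_signal(r1_grid, 30.0, protocol, m0=1.0)
        assert np.all(np.diff(s) > 0)
        assert np.all((s >= 0) & (s <= 1.0))
        r2_grid = np.linspace(0.0, 1000.0, 80)
        s2 = spgr_signal(12.0, r2_grid, protocol, m0=1.0)
        assert np.all(np.diff(s2) < 0)

    def test_negative_rates_raise(self, protocol):
        with pytest.raises(ValueError):
            spgr_signal(-1.0, 0.0, protocol)


class TestSimulateVoxel:
    def _vm(self, **kw):
        defaults = dict(
            kinetics=KineticParams(k12=0.045, k23=0.059, c1=0.104),
            aggregation=AggregationSchedule(
                r2agg_elevation=15.8, r2agg_reduction=370.0, r2agg_recovery=73.5,
                t_formation=5, t_clearance=11,
            ),
            v23=0.75,
            m0=1000.0,
        )
        defaults.update(kw)
        return VoxelModel(**defaults)

    def test_pure_c2_no_aggregation_is_nondecreasing(self, protocol, relaxivity):
        vm = self._vm(aggregation=AggregationSchedule(), v23=1.0)
        curve = simulate_voxel(vm, protocol, relaxivity)
        assert np.all(np.diff(curve.values) >= -1e-12)
        # equals the single-compartment enhancement curve
        cc = solve_compartments(vm.kinetics, protocol.times)
        expected = vm.m0 * spgr_signal(
            relaxivity.baseline_r1 + relaxivity.r1 * cc.c2,
            relaxivity.baseline_r2star + relaxivity.r2 * cc.c2,
            protocol,
        )
        np.testing.assert_allclose(curve.values, expected, rtol=1e-12)

    def test_raising_reduction_rate_only_touches_reduction_window(self, protocol, relaxivity):
        base = simulate_voxel(self._vm(), protocol, relaxivity).values
        worse = simulate_voxel(
            self._vm(
                aggregation=AggregationSchedule(
                    r2agg_elevation=15.8, r2agg_reduction=500.0, r2agg_recovery=73.5,
                    t_formation=5, t_clearance=11,
                )
            ),
            protocol, relaxivity,
        ).values
        np.testing.assert_array_equal(base[:5], worse[:5])
        np.testing.assert_array_equal(base[11:], worse[11:])
        assert np.all(worse[5:11] < base[5:11])

    def test_three_phase_curve_minimum_in_reduction_window(self, protocol, relaxivity):
        curve = simulate_voxel(self._vm(), protocol, relaxivity).values
        assert 5 <= int(np.argmin(curve)) < 11

    def test_scales_exactly_with_m0(self, protocol, relaxivity):
        c1 = simulate_voxel(self._vm(m0=1.0), protocol, relaxivity).values
        c2 = simulate_voxel(self._vm(m0=137.0), protocol, relaxivity).values
        np.testing.assert_allclose(c2, 137.0 * c1, rtol=1e-12)

    def test_invalid_schedule_raises(self):
        with pytest.raises(ValueError):
            AggregationSchedule(t_formation=10, t_clearance=5)
        with pytest.raises(ValueError):
            VoxelModel(
                kinetics=KineticParams(k12=0.1, k23=0.1),
                aggregation=AggregationSchedule(),
                v23=1.5,
            )
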