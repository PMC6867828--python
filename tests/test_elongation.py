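"""Cycle model, stochastic simulators, velocity estimation and curve fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import actinpace as ap
from actinpace.elongation import END_CAPPED_PRE, END_CAPPED_POST, END_FREE
from actinpace.synthetic import WT_CYCLE_RATES, gen_velocity_curve

RATES = ap.CycleRates(k_bind=5e7, k_trans=5000.0, k_release=556.0)

rate_strategy = st.builds(
    ap.CycleRates,
    k_bind=st.floats(1e5, 1e9),
    k_trans=st.floats(1.0, 1e6),
    k_release=st.floats(1.0, 1e6),
)


class TestCycleVelocity:
    def test_zero_concentration_gives_zero(self):
        assert ap.cycle_velocity(RATES, 0.0) == 0.0

    def test_release_limited_plateau(self):
        """With a fast transition, the plateau is the release rate itself."""
        rates = ap.CycleRates(k_bind=5e7, k_trans=1e12, k_release=500.0)
        assert ap.cycle_velocity(rates, 1.0) == pytest.approx(500.0, rel=1e-3)

    def test_harmonic_sum_value(self):
        """Direct arithmetic: 1/(1/5000 + 1/5000 + 1/556) s^-1 at 100 uM."""
        expected = 1.0 / (1.0 / 5000.0 + 1.0 / 5000.0 + 1.0 / 556.0)
        assert ap.cycle_velocity(RATES, 100e-6) == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(454.84, abs=0.01)

    @given(rates=rate_strategy)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exactly_hyperbolic(self, rates):
        """max |v(c) - hyperbola| / v_max < 1e-12 over a dense grid."""
        fit = ap.hyperbolic_params_from_cycle(rates)
        c = np.geomspace(0.01, 100, 200) * fit.k_half
        dev = np.abs(ap.cycle_velocity(rates, c) - fit.velocity(c)) / fit.v_max
        assert dev.max() < 1e-12

    @given(rates=rate_strategy)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_half_saturation_identity(self, rates):
        fit = ap.hyperbolic_params_from_cycle(rates)
        assert ap.cycle_velocity(rates, fit.k_half) == pytest.approx(
            fit.v_max / 2.0, rel=1e-12
        )

    def test_doubling_k_bind_halves_k_half_only(self):
        f1 = ap.hyperbolic_params_from_cycle(RATES)
        f2 = ap.hyperbolic_params_from_cycle(
            ap.CycleRates(2 * RATES.k_bind, RATES.k_trans, RATES.k_release)
        )
        assert f2.v_max == f1.v_max
        assert f2.k_half == pytest.approx(f1.k_half / 2.0, rel=1e-12)

    def test_vmax_monotone_in_first_order_rates_not_k_bind(self):
        base = ap.hyperbolic_params_from_cycle(RATES).v_max
        faster_rel = ap.hyperbolic_params_from_cycle(
            ap.CycleRates(RATES.k_bind, RATES.k_trans, 2 * RATES.k_release)
        ).v_max
        faster_trans = ap.hyperbolic_params_from_cycle(
            ap.CycleRates(RATES.k_bind, 2 * RATES.k_trans, RATES.k_release)
        ).v_max
        other_bind = ap.hyperbolic_params_from_cycle(
            ap.CycleRates(3 * RATES.k_bind, RATES.k_trans, RATES.k_release)
        ).v_max
        assert faster_rel > base and faster_trans > base and other_bind == base


class TestForminModification:
    def test_identity_factors(self):
        assert ap.apply_formin(RATES, ap.ForminFactors(1.0, 1.0)) == RATES

    def test_release_acceleration_sets_plateau_ratio(self):
        """f_release = 4 with fast transition gives a ~4x higher plateau."""
        rates = ap.CycleRates(k_bind=5e7, k_trans=1e9, k_release=500.0)
        accel = ap.apply_formin(rates, ap.ForminFactors(1.0, 4.0))
        ratio = (
            ap.hyperbolic_params_from_cycle(accel).v_max
            / ap.hyperbolic_params_from_cycle(rates).v_max
        )
        assert ratio == pytest.approx(4.0, rel=1e-5)

    def test_equal_factors_give_uniform_enhancement(self):
        """f_bind = f_release = f scales the velocity by f at every conc."""
        rates = ap.CycleRates(k_bind=5e7, k_trans=1e9, k_release=500.0)
        f = ap.ForminFactors(3.0, 3.0)
        c = np.geomspace(0.1, 50, 30) * 1e-6
        enh = ap.relative_enhancement(rates, f, c)
        assert np.allclose(enh, 3.0, rtol=1e-6)

    def test_enhancement_limits_and_monotonicity(self):
        f = ap.ForminFactors(6.0, 4.0)
        fit = ap.hyperbolic_params_from_cycle(RATES)
        c = np.geomspace(1e-4, 1e4, 300) * fit.k_half
        enh = ap.relative_enhancement(RATES, f, c)
        vr = (
            ap.hyperbolic_params_from_cycle(ap.apply_formin(RATES, f)).v_max
            / fit.v_max
        )
        assert ap.relative_enhancement(RATES, f, 0.0) == pytest.approx(6.0)
        assert enh[0] == pytest.approx(6.0, rel=1e-3)
        assert enh[-1] == pytest.approx(vr, rel=1e-3)
        assert np.all(np.diff(enh) < 0)
        assert np.all((enh <= 6.0 + 1e-12) & (enh >= vr - 1e-12))


class TestCycleSimulator:
    def test_zero_concentration_never_grows(self):
        traj = ap.simulate_filament(RATES, 0.0, 10.0, seed=1)
        assert traj.times.size == 0

    def test_same_seed_bitwise_identical(self):
        t1 = ap.simulate_filament(RATES, 20e-6, 5.0, seed=99)
        t2 = ap.simulate_filament(RATES, 20e-6, 5.0, seed=99)
        assert np.array_equal(t1.times, t2.times)
        assert np.array_equal(t1.lengths, t2.lengths)
        assert np.array_equal(t1.end_state, t2.end_state)

    def test_event_structure_is_the_three_step_cycle(self):
        traj = ap.simulate_filament(RATES, 10e-6, 0.5, seed=5)
        assert np.all(np.diff(traj.times) > 0)
        assert np.all(np.diff(traj.lengths) >= 0)
        assert set(np.unique(np.diff(traj.lengths))) <= {0, 1}
        # states cycle pre -> post -> free
        expected = np.tile([END_CAPPED_PRE, END_CAPPED_POST, END_FREE],
                           traj.times.size // 3 + 1)[: traj.times.size]
        assert np.array_equal(traj.end_state, expected)

    def test_mean_velocity_matches_analytic(self):
        """Grand mean over filaments within 3 SEM of the cycle velocity."""
        fit = ap.hyperbolic_params_from_cycle(RATES)
        conc = 10.0 * fit.k_half
        seeds = np.random.SeedSequence(321).spawn(60)
        vs = []
        for s in seeds:
            traj = ap.simulate_filament(RATES, conc, 5.0, seed=s)
            vs.append(ap.estimate_trajectory_velocity(traj)[0])
        vs = np.array(vs)
        sem = vs.std(ddof=1) / np.sqrt(vs.size)
        assert abs(vs.mean() - ap.cycle_velocity(RATES, conc)) < 3 * sem

    def test_event_cap_truncation_carries_partial_trajectory(self):
        with pytest.raises(ap.TrajectoryTruncatedError) as exc:
            ap.simulate_filament(RATES, 100e-6, 1000.0, seed=0, event_cap=300)
        traj = exc.value.trajectory
        assert traj is not None and traj.times.size <= 300


class TestBareSimulator:
    def test_no_depolymerization_means_monotone_growth(self):
        rates = ap.BareActinRates(k_plus=1e7, k_minus=0.0)
        traj = ap.simulate_bare_filament(rates, 2e-6, 5.0, seed=4)
        assert np.all(np.diff(traj.lengths) == 1)

    def test_critical_concentration_balances(self):
        """At c = k_minus / k_plus the mean growth velocity is ~0."""
        rates = ap.BareActinRates(k_plus=1e7, k_minus=10.0)
        conc = rates.k_minus / rates.k_plus
        seeds = np.random.SeedSequence(17).spawn(40)
        vs = []
        for s in seeds:
            traj = ap.simulate_bare_filament(rates, conc, 20.0, seed=s,
                                             start_length=500)
            vs.append(ap.estimate_trajectory_velocity(traj)[0])
        vs = np.array(vs)
        sem = vs.std(ddof=1) / np.sqrt(vs.size)
        assert abs(vs.mean()) < 3 * max(sem, 0.1)

    def test_mean_velocity_is_gain_minus_loss(self):
        rates = ap.BareActinRates(k_plus=1.16e7, k_minus=1.4)
        conc = 5e-6
        seeds = np.random.SeedSequence(55).spawn(50)
        vs = []
        for s in seeds:
            traj = ap.simulate_bare_filament(rates, conc, 10.0, seed=s,
                                             start_length=100)
            vs.append(ap.estimate_trajectory_velocity(traj)[0])
        vs = np.array(vs)
        expected = rates.k_plus * conc - rates.k_minus
        sem = vs.std(ddof=1) / np.sqrt(vs.size)
        assert abs(vs.mean() - expected) < 3 * sem

    def test_length_floored_at_zero(self):
        rates = ap.BareActinRates(k_plus=1e5, k_minus=50.0)
        traj = ap.simulate_bare_filament(rates, 1e-7, 5.0, seed=9, start_length=3)
        assert np.all(traj.lengths >= 0)


class TestVelocityEstimation:
    def test_exact_linear_trajectory(self):
        times = np.linspace(0.1, 10, 50)
        # a truly linear record: length = 5 t
        traj = ap.FilamentTrajectory(
            times=times, lengths=5.0 * times, end_state=np.zeros(50, dtype=np.int8),
            seed=0, params={"start_length": 0},
        )
        v, err = ap.estimate_trajectory_velocity(traj)
        assert v == pytest.approx(5.0, rel=1e-12)
        assert err == pytest.approx(0.0, abs=1e-9)

    def test_subunit_rise_conversion(self):
        assert ap.RISE_PER_SUBUNIT_NM == 2.7
        from actinpace.units import subunits_per_s_to_um_per_s
        assert subunits_per_s_to_um_per_s(1.0) == pytest.approx(2.7e-3)
        assert subunits_per_s_to_um_per_s(1450.0) == pytest.approx(3.915)

    def test_single_event_rejected(self):
        traj = ap.FilamentTrajectory(np.array([1.0]), np.array([1]),
                                     np.array([0], dtype=np.int8), 0, {})
        with pytest.raises(ap.InvalidInputError):
            ap.estimate_trajectory_velocity(traj)


class TestCurveFits:
    def test_exact_hyperbola_recovered(self):
        c = np.geomspace(1, 175, 12) * 1e-6
        truth = ap.HyperbolicFit(v_max=500.0, k_half=20e-6)
        curve = ap.VelocityCurve(c, truth.velocity(c), np.full(12, 10.0), np.full(12, 40))
        fit = ap.fit_hyperbolic(curve)
        assert fit.v_max == pytest.approx(500.0, rel=1e-6)
        assert fit.k_half == pytest.approx(20e-6, rel=1e-6)

    def test_simulated_curve_recovery(self):
        """End-to-end: stochastic curve -> hyperbolic fit within 10 %."""
        curve, truth = gen_velocity_curve(seed=8, n_filaments=15, duration=10.0,
                                          mode="simulate")
        fit = ap.fit_hyperbolic(curve)
        assert fit.v_max == pytest.approx(truth["v_max"], rel=0.10)
        assert fit.k_half == pytest.approx(truth["k_half"], rel=0.10)

    def test_mutant_release_scaling_orders_plateaus(self):
        """Plateau ordering follows the release rate: tight-binder < wt <
        E82A-like < R88K-like."""
        scales = [0.2, 1.0, 1.5, 4.0]
        fits = []
        for i, s in enumerate(scales):
            rates = ap.CycleRates(RATES.k_bind, RATES.k_trans, RATES.k_release * s)
            curve, _ = gen_velocity_curve(seed=100 + i, rates=rates, mode="fast")
            fits.append(ap.fit_hyperbolic(curve).v_max)
        assert fits == sorted(fits)

    def test_linear_regime_slope_is_k_bind(self):
        fit_true = ap.hyperbolic_params_from_cycle(RATES)
        c = np.linspace(0.002, 0.05, 10) * fit_true.k_half
        curve = ap.VelocityCurve(c, ap.cycle_velocity(RATES, c),
                                 np.full(10, 5.0), np.full(10, 40))
        lin = ap.fit_linear_regime(curve, conc_cutoff=c.max())
        assert lin.slope == pytest.approx(RATES.k_bind, rel=0.05)

    def test_linear_regime_requires_points_below_cutoff(self):
        c = np.linspace(10, 60, 6) * 1e-6
        curve = ap.VelocityCurve(c, ap.cycle_velocity(RATES, c),
                                 np.full(6, 5.0), np.full(6, 40))
        with pytest.raises(ap.InvalidInputError):
            ap.fit_linear_regime(curve, conc_cutoff=1e-6)


class TestBuffering:
    fit = ap.HyperbolicFit(v_max=500.0, k_half=10e-6)

    def test_saturated_regime_ratio_near_one(self):
        assert ap.buffering_ratio(self.fit, 100 * self.fit.k_half, 3.0) == pytest.approx(
            1.0, abs=0.01
        )

    def test_linear_regime_ratio_equals_fold(self):
        assert ap.buffering_ratio(self.fit, self.fit.k_half * 1e-4, 3.0) == pytest.approx(
            3.0, rel=1e-3
        )

    def test_three_fold_rise_at_five_k_half(self):
        """(15/16)/(5/6) = 1.125: a 3x concentration rise moves the speed
        by only 12.5% at 5x the half-saturation point."""
        assert ap.buffering_ratio(self.fit, 5 * self.fit.k_half, 3.0) == pytest.approx(
            1.125, rel=1e-12
        )

    def test_buffered_bound_beyond_five_k_half(self):
        for mult in (5, 8, 20, 100):
            assert ap.buffering_ratio(self.fit, mult * self.fit.k_half, 3.0) <= 1.13
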