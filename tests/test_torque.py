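"""Torque computation, unwinding conversion, twist binning, and linear fits."""

import math

import numpy as np
import pytest

import aurbt as ab
from aurbt import (OUParams, StateModel, StateSpec, TetherSpec, TriangularRamp,
                   compute_torque, fit_tether_stiffness, fit_twist_dependence,
                   bin_kinetics_by_twist, torque_to_unwinding, twist_density,
                   twist_landscape, transition_rates)
from aurbt.torque import TorqueSeries, TwistBin
from aurbt.kinetics import RateEstimate
from aurbt.synth import TWO_PI
from conftest import make_dwells


class TestComputeTorque:
    def test_zero_deflection_gives_zero_torque(self, tether, spec3, ou):
        trace, _ = ab.simulate_ramp_trace(spec3, ou, tether, None, duration=1.0,
                                          dt=1e-3, seed=0)
        trace.rotor_turns = trace.magnet_turns.copy()
        ts = compute_torque(trace)
        np.testing.assert_array_equal(ts.torque_pNnm, 0.0)

    def test_one_turn_deflection_unit_conversion(self, tether, spec3, ou):
        # kappa_t = 0.26 pN nm/rad -> 0.26 * 2 pi per turn of deflection
        trace, _ = ab.simulate_ramp_trace(spec3, ou, tether, None, duration=1.0,
                                          dt=1e-3, seed=0)
        trace.rotor_turns = trace.magnet_turns - 1.0
        ts = compute_torque(trace)
        np.testing.assert_allclose(ts.torque_pNnm, 0.26 * TWO_PI, atol=1e-12)

    def test_relaxed_trace_rejected(self, tether, spec3, ou):
        trace, _ = ab.simulate_relaxed_trace(spec3, ou, tether, duration=1.0, seed=0)
        with pytest.raises(ValueError, match="ramp"):
            compute_torque(trace)

    def test_round_trip_recovers_generator_torque(self, tether, spec3):
        trace, truth = ab.simulate_ramp_trace(spec3, OUParams(0.005, 0.0), tether,
                                              None, duration=30.0, dt=1e-3, seed=1)
        ts = compute_torque(trace)
        x = truth.unwinding_at(trace.times)
        tau_true = tether.kappa_turn * (trace.magnet_turns + x / tether.helicity)
        np.testing.assert_allclose(ts.torque_pNnm, tau_true, atol=1e-10)


class TestTetherStiffness:
    def test_exact_line_recovered_exactly(self, tether):
        theta = np.linspace(-5, 7.5, 500)
        tau = tether.kappa_turn * theta
        kappa, intercept = fit_tether_stiffness(tau, theta)
        assert kappa == pytest.approx(tether.kappa_rad, rel=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-9)

    def test_noisy_closed_state_ramp_within_2_percent(self, tether):
        spec = StateSpec(labels=("C",), unwinding_bp=(0.0,), base_rates={})
        trace, _ = ab.simulate_ramp_trace(spec, OUParams(0.005, 0.05), tether,
                                          None, duration=200.0, dt=1e-3, seed=2)
        ts = compute_torque(trace)
        kappa, _ = fit_tether_stiffness(ts.torque_pNnm, ts.theta_turns)
        assert kappa == pytest.approx(tether.kappa_rad, rel=0.02)

    def test_constant_twist_not_identifiable(self):
        with pytest.raises(ValueError, match="variance"):
            fit_tether_stiffness(np.ones(100), np.zeros(100))


class TestTorqueToUnwinding:
    def test_bdna_torque_gives_zero_unwinding(self, tether):
        theta = np.linspace(-2, 2, 50)
        ts = TorqueSeries(theta_turns=theta, torque_pNnm=tether.kappa_turn * theta)
        out = torque_to_unwinding(ts, tether.kappa_rad)
        np.testing.assert_allclose(out.unwound_bp, 0.0, atol=1e-12)

    def test_torque_excess_of_kappa_gives_one_helical_turn(self, tether):
        theta = np.zeros(5)
        ts = TorqueSeries(theta_turns=theta,
                          torque_pNnm=np.full(5, TWO_PI * tether.kappa_rad))
        out = torque_to_unwinding(ts, tether.kappa_rad, helicity=10.5)
        np.testing.assert_allclose(out.unwound_bp, 10.5, atol=1e-12)

    def test_forced_intermediate_dwell_reads_7_bp(self, tether):
        # noiseless ramp locked in the ~7 bp intermediate: algebraic inversion
        spec = StateSpec(labels=("I",), unwinding_bp=(7.0,), base_rates={})
        trace, _ = ab.simulate_ramp_trace(spec, OUParams(0.005, 0.0), tether,
                                          None, duration=30.0, dt=1e-3, seed=0)
        ts = torque_to_unwinding(compute_torque(trace), tether.kappa_rad,
                                 tether.helicity)
        np.testing.assert_allclose(ts.unwound_bp, 7.0, atol=1e-9)

    def test_nonpositive_kappa_rejected(self, tether):
        ts = TorqueSeries(theta_turns=np.zeros(3), torque_pNnm=np.zeros(3))
        with pytest.raises(ValueError):
            torque_to_unwinding(ts, 0.0)


class TestTwistDensity:
    def test_zero_turns(self, tether):
        assert twist_density(0.0, tether) == 0.0

    def test_minus_five_turns_on_5kb_tether_is_about_one_percent(self):
        tether = TetherSpec(length_bp=5000, helicity=10.5)
        assert twist_density(-5.0, tether) == pytest.approx(-1.05)

    def test_direct_arithmetic(self):
        tether = TetherSpec(length_bp=2100, helicity=10.5)
        assert twist_density(-10.0, tether) == pytest.approx(-5.0)


class TestBinKinetics:
    def test_single_bin_reduces_to_plain_rate_estimator(self):
        entries = [("C", 4, 0), ("I", 1, 7), ("C", 6, 0), ("I", 2, 7),
                   ("C", 3, 0), ("I", 5, 7), ("C", 2, 0)]
        dwells = make_dwells(entries)
        bins = bin_kinetics_by_twist(dwells, 0.0, bin_width_turns=100.0,
                                     min_transitions=1)
        assert len(bins) == 1
        plain = {r.pair: r for r in transition_rates(
            dwells, count_from_first_transition=False)}
        for r in bins[0].rates:
            assert r.rate == pytest.approx(plain[r.pair].rate, rel=1e-9)
            assert r.n_transitions == plain[r.pair].n_transitions

    def test_hand_built_exclusion_rule(self):
        # state C: 4 s in bin A with 2 exits (dropped, < 3), 2 s in bin B
        # with 3 exits -> k = 1.5 1/s
        entries = []
        for _ in range(2):
            entries += [("C", 2.0, 0.0), ("I", 0.5, 7.0)]   # exits in bin A
        for _ in range(3):
            entries += [("C", 2.0 / 3, 0.0), ("I", 0.5, 7.0)]  # exits in bin B
        dwells = make_dwells(entries)
        t_split = 2 * 2.0 + 2 * 0.5  # C time in bin A ends here

        def theta(t):
            return np.where(np.asarray(t) < t_split, 0.25, 0.75)

        bins = bin_kinetics_by_twist(dwells, theta, bin_width_turns=0.5,
                                     theta_range=(0.0, 1.0), occupancy_dt=1e-3)
        by_center = {round(b.theta_center, 2): b for b in bins}
        assert 0.25 not in by_center or by_center[0.25].rate_for(("C", "I")) is None
        r = by_center[0.75].rate_for(("C", "I"))
        assert r.n_transitions == 3
        assert r.rate == pytest.approx(1.5, rel=1e-6)

    def test_no_reported_rate_below_three_transitions(self, tether, two_state_spec):
        ramp = TriangularRamp()
        path = ab.simulate_state_path(two_state_spec, 2 * ramp.period, ramp,
                                      tether, seed=3)
        bins = bin_kinetics_by_twist(path.to_dwells(), ramp)
        assert bins, "expected populated twist bins"
        for b in bins:
            for r in b.rates:
                assert r.n_transitions >= 3

    def test_binned_rates_match_generator_at_bin_centers(self, tether, two_state_spec):
        ramp = TriangularRamp()
        path = ab.simulate_state_path(two_state_spec, 6 * ramp.period, ramp,
                                      tether, seed=4)
        bins = bin_kinetics_by_twist(path.to_dwells(), ramp)
        checked = 0
        for b in bins:
            for r in b.rates:
                true = two_state_spec.rate(*r.pair, b.theta_center, tether.beta_kappa)
                # 3 se plus headroom for within-bin rate variation
                if r.n_transitions >= 10:
                    assert abs(r.rate - true) < 3 * r.se + 0.15 * true
                    checked += 1
        assert checked >= 8


class TestFitTwistDependence:
    @staticmethod
    def bins_on_line(slope, intercept, thetas, n=100):
        """Synthetic bins whose ln K (and ln k_fwd) lie exactly on a line."""
        out = []
        for th in thetas:
            k_fwd = math.exp(slope * th + intercept)
            out.append(TwistBin(theta_center=th, rates=[
                RateEstimate.from_counts(("C", "I"), n, n / k_fwd),
                RateEstimate.from_counts(("I", "C"), n, n),
            ]))
        return out

    def test_exact_line_recovers_slope_intercept_and_conversions(self):
        # ln K = 2 theta + 1 with beta kappa = 4 per turn^2:
        # dtheta = 0.5 turns, dG(0) = -1 kBT
        kBT = 4.114
        tether = TetherSpec(kappa_rad=4.0 * kBT / (TWO_PI * TWO_PI))
        assert tether.beta_kappa == pytest.approx(4.0)
        bins = self.bins_on_line(2.0, 1.0, np.linspace(-2, 2, 9))
        (fit,) = fit_twist_dependence(bins, tether, pairs=[("C", "I")])
        assert fit.slope_lnK == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept_lnK == pytest.approx(1.0, abs=1e-9)
        assert fit.delta_theta_turns == pytest.approx(0.5, abs=1e-9)
        assert fit.dG0_kBT == pytest.approx(-1.0, abs=1e-9)
        # here the reverse rate is twist-independent, so barrier fraction = 1
        assert fit.barrier_fraction == pytest.approx(1.0, abs=1e-9)

    def test_zero_slope_means_twist_independent_equilibrium(self, tether):
        bins = self.bins_on_line(0.0, 0.7, np.linspace(-3, 3, 7))
        (fit,) = fit_twist_dependence(bins, tether, pairs=[("C", "I")])
        assert fit.delta_theta_turns == pytest.approx(0.0, abs=1e-9)

    def test_single_theta_degenerate_rejected(self, tether):
        bins = self.bins_on_line(1.0, 0.0, [0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="single twist"):
            fit_twist_dependence(bins, tether, pairs=[("C", "I")])

    def test_parameter_recovery_from_ramp_simulation(self, tether, two_state_spec):
        ramp = TriangularRamp()
        path = ab.simulate_state_path(two_state_spec, 5 * ramp.period, ramp,
                                      tether, seed=11)
        bins = bin_kinetics_by_twist(path.to_dwells(), ramp)
        (fit,) = fit_twist_dependence(bins, tether, pairs=[("C", "I")])
        true_dtheta = two_state_spec.delta_theta[("C", "I")]
        assert fit.delta_theta_turns == pytest.approx(true_dtheta, rel=0.15)
        assert fit.dG0_kBT == pytest.approx(3.0, abs=0.5)

    def test_lnK_slope_consistent_with_rate_slopes(self, tether, two_state_spec):
        # slope(ln K) = slope(ln k_fwd) - slope(ln k_rev) within fit errors
        ramp = TriangularRamp()
        path = ab.simulate_state_path(two_state_spec, 5 * ramp.period, ramp,
                                      tether, seed=12)
        bins = bin_kinetics_by_twist(path.to_dwells(), ramp)
        (f_fwd,) = fit_twist_dependence(bins, tether, pairs=[("C", "I")])
        (f_rev,) = fit_twist_dependence(bins, tether, pairs=[("I", "C")])
        diff = f_fwd.slope_lnk_fwd - f_rev.slope_lnk_fwd
        err = 3 * math.hypot(f_fwd.se_slope_lnk_fwd, f_rev.se_slope_lnk_fwd) \
            + 3 * f_fwd.se_slope_lnK
        assert abs(diff - f_fwd.slope_lnK) < err


class TestTwistLandscape:
    @staticmethod
    def fits(dg0=3.0, slope=-1.5, bf=0.4):
        from aurbt.torque import TwistFit
        return [TwistFit(pair=("C", "I"), slope_lnK=slope, intercept_lnK=-dg0,
                         se_slope_lnK=0.0, se_intercept_lnK=0.0,
                         delta_theta_turns=slope / 2.3, dG0_kBT=dg0,
                         slope_lnk_fwd=bf * slope, se_slope_lnk_fwd=0.0,
                         lnk0_fwd=math.log(0.2), barrier_fraction=bf, n_bins=10)]

    def model(self):
        return StateModel(labels=("C", "I"), centers_bp=np.array([0.0, 7.0]))

    def test_zero_twist_wells_equal_intercept_energies(self):
        ls = twist_landscape(self.fits(dg0=3.0), self.model(), theta=0.0)
        np.testing.assert_allclose(ls.well_energy_kBT, [0.0, 3.0], atol=1e-12)

    def test_barrier_at_destination_well_when_fraction_is_one(self):
        ls = twist_landscape(self.fits(bf=1.0), self.model(), theta=0.0)
        assert ls.barrier_x_bp[0] == pytest.approx(7.0)

    def test_negative_twist_lowers_unwound_well_by_slope_times_theta(self):
        slope = -1.5
        ls0 = twist_landscape(self.fits(slope=slope), self.model(), theta=0.0)
        ls5 = twist_landscape(self.fits(slope=slope), self.model(), theta=-5.0)
        drop = ls0.well_energy_kBT[1] - ls5.well_energy_kBT[1]
        assert drop == pytest.approx(slope * -5.0, abs=1e-9)  # 7.5 kBT stabilization
        assert ls5.well_energy_kBT[1] < ls0.well_energy_kBT[1]
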