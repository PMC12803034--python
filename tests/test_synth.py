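"""Generator correctness: CTMC switching, OU noise, ramp observables."""

import math

import numpy as np
import pytest
from scipy import linalg

import aurbt as ab
from aurbt.synth import _ou_series, DEFAULT_CLEAVAGE_TIMES_MIN


def dwell_durations(path):
    edges = np.concatenate([[0.0], path.switch_times, [path.duration]])
    return np.diff(edges)


class TestStatePath:
    def test_single_state_spans_duration(self, tether):
        spec = ab.StateSpec(labels=("C",), unwinding_bp=(0.0,), base_rates={})
        path = ab.simulate_state_path(spec, 5.0, 0.0, tether, seed=0)
        assert len(path.switch_times) == 0
        assert path.state_labels == ["C"]

    def test_symmetric_two_state_mean_dwell(self, tether):
        # CTMC: mean dwell = 1 / exit rate = 1 s for k12 = k21 = 1/s
        spec = ab.StateSpec(labels=("A", "B"), unwinding_bp=(0.0, 7.0),
                            base_rates={("A", "B"): 1.0, ("B", "A"): 1.0})
        path = ab.simulate_state_path(spec, 10_000.0, 0.0, tether, seed=1)
        d = dwell_durations(path)
        states = np.array(path.state_labels)
        for s in ("A", "B"):
            assert d[states == s].mean() == pytest.approx(1.0, rel=0.05)

    def test_three_state_occupancy_matches_generator_matrix(self, tether, spec3):
        # independent oracle: stationary distribution of the generator matrix
        labels = spec3.labels
        Q = np.zeros((3, 3))
        for (i, j), k in spec3.base_rates.items():
            a, b = labels.index(i), labels.index(j)
            Q[a, b] = k
        Q -= np.diag(Q.sum(axis=1))
        pi = linalg.null_space(Q.T)[:, 0]
        pi /= pi.sum()

        path = ab.simulate_state_path(spec3, 20_000.0, 0.0, tether, seed=2)
        d = dwell_durations(path)
        states = np.array(path.state_labels)
        occ = np.array([d[states == s].sum() for s in labels]) / path.duration
        assert np.allclose(occ, pi, atol=0.02)
        # I sits between C and O in occupancy when I -> C dominates
        assert pi[0] > pi[1] > pi[2]
        assert occ[0] > occ[1] > occ[2]

    def test_transition_counts_within_poisson_3sigma(self, tether, spec3):
        # pooled over several runs so a single unlucky draw cannot dominate
        occ = {s: 0.0 for s in spec3.labels}
        counts = {}
        for seed in range(3, 9):
            path = ab.simulate_state_path(spec3, 10_000.0, 0.0, tether, seed=seed)
            d = dwell_durations(path)
            states = np.array(path.state_labels)
            for s in spec3.labels:
                occ[s] += d[states == s].sum()
            for a, b in zip(path.state_labels[:-1], path.state_labels[1:]):
                counts[(a, b)] = counts.get((a, b), 0) + 1
        for pair, k in spec3.base_rates.items():
            expected = k * occ[pair[0]]
            assert abs(counts.get(pair, 0) - expected) < 3 * math.sqrt(expected)

    def test_ratio_law_is_exact_analytically(self, tether, two_state_spec):
        # k_ij(theta)/k_ji(theta) = K_ij(0) exp(beta kappa dtheta theta), evaluated
        # from the rate law itself, not sampled
        spec, bk = two_state_spec, tether.beta_kappa
        K0 = spec.base_rates[("C", "I")] / spec.base_rates[("I", "C")]
        for theta in (-5.0, -1.3, 0.0, 2.0, 7.5):
            ratio = spec.rate("C", "I", theta, bk) / spec.rate("I", "C", theta, bk)
            expected = K0 * math.exp(bk * spec.delta_theta[("C", "I")] * theta)
            assert ratio == pytest.approx(expected, rel=1e-12)

    def test_nonfinite_rate_rejected_with_pair_name(self, tether):
        spec = ab.StateSpec(labels=("C", "I"), unwinding_bp=(0.0, 7.0),
                            base_rates={("C", "I"): np.inf, ("I", "C"): 1.0})
        with pytest.raises(ValueError, match="C->I"):
            ab.simulate_state_path(spec, 1.0, 0.0, tether, seed=0)

    def test_negative_duration_rejected(self, tether, spec3):
        with pytest.raises(ValueError):
            ab.simulate_state_path(spec3, -1.0, 0.0, tether, seed=0)


class TestRelaxedTrace:
    def test_noiseless_trace_equals_state_means(self, tether, spec3):
        trace, truth = ab.simulate_relaxed_trace(
            spec3, ab.OUParams(0.005, 0.0), tether, duration=20.0, seed=4)
        mu = truth.unwinding_at(trace.times) / tether.helicity
        np.testing.assert_array_equal(trace.rotor_turns, mu)

    def test_instrument_defaults(self, tether, spec3, ou):
        # 5 kHz sampling; C/I/O at 0/7/14 bp unwound
        trace, _ = ab.simulate_relaxed_trace(spec3, ou, tether, duration=1.0, seed=0)
        assert trace.dt == pytest.approx(1.0 / 5000.0)
        assert spec3.unwinding_bp == (0.0, 7.0, 14.0)

    def test_ou_stationarity_and_autocorrelation(self, tether):
        ou = ab.OUParams(tau_c=0.005, sigma=0.05)
        spec = ab.StateSpec(labels=("C",), unwinding_bp=(0.0,), base_rates={})
        trace, _ = ab.simulate_relaxed_trace(spec, ou, tether, duration=100.0, seed=5)
        y = trace.rotor_turns
        assert y.std() == pytest.approx(ou.sigma, rel=0.03)
        d = y - y.mean()
        r1 = (d[1:] @ d[:-1]) / (d @ d)
        assert r1 == pytest.approx(math.exp(-trace.dt / ou.tau_c), abs=0.01)
        tau_est = -trace.dt / math.log(r1)
        assert tau_est == pytest.approx(ou.tau_c, rel=0.05)

    def test_identical_seed_reproduces_bit_identical_trace(self, tether, spec3, ou):
        t1, _ = ab.simulate_relaxed_trace(spec3, ou, tether, duration=5.0, seed=9)
        t2, _ = ab.simulate_relaxed_trace(spec3, ou, tether, duration=5.0, seed=9)
        np.testing.assert_array_equal(t1.rotor_turns, t2.rotor_turns)

    def test_warns_when_dt_exceeds_tau_c(self, tether, spec3):
        with pytest.warns(UserWarning, match="tau_c"):
            ab.simulate_relaxed_trace(spec3, ab.OUParams(1e-5, 0.05), tether,
                                      duration=0.5, seed=0)

    def test_bead_relaxes_through_tau_c_after_switch(self):
        # the observable mean-reverts to a new level instead of jumping
        ou = ab.OUParams(tau_c=0.01, sigma=1e-12)
        mu = np.concatenate([np.zeros(100), np.ones(100)])
        y = _ou_series(mu, ou, 0.001, np.random.default_rng(0))
        a = math.exp(-0.001 / 0.01)
        # first post-switch sample: 1 + (y_prev - 1) a
        assert y[100] == pytest.approx(1.0 + (y[99] - 1.0) * a, abs=1e-9)


class TestRampTrace:
    def test_ramp_defaults_match_protocol(self):
        ramp = ab.TriangularRamp()
        assert (ramp.low, ramp.high, ramp.rate_rpm) == (-5.0, 7.5, 3.0)

    def test_triangular_wave_bounds_and_rate(self):
        ramp = ab.TriangularRamp(low_turns=-5, high_turns=7.5, rate_rpm=3)
        t = np.linspace(0, 3 * ramp.period, 40_001)
        th = ramp(t)
        assert th.min() >= -5 - 1e-12 and th.max() <= 7.5 + 1e-12
        slopes = np.abs(np.diff(th) / np.diff(t))
        assert np.median(slopes) == pytest.approx(3.0 / 60.0, rel=1e-6)

    def test_closed_only_noiseless_torque_is_bdna_line(self, tether):
        spec = ab.StateSpec(labels=("C",), unwinding_bp=(0.0,), base_rates={})
        trace, _ = ab.simulate_ramp_trace(spec, ab.OUParams(0.005, 0.0), tether,
                                          None, duration=30.0, dt=1e-3, seed=0)
        ts = ab.compute_torque(trace)
        np.testing.assert_allclose(ts.torque_pNnm,
                                   tether.kappa_turn * ts.theta_turns, atol=1e-12)

    def test_invalid_ramp_parameters(self):
        with pytest.raises(ValueError):
            ab.TriangularRamp(low_turns=2.0, high_turns=2.0)
        with pytest.raises(ValueError):
            ab.TriangularRamp(rate_rpm=0.0)

    def test_magnet_series_present_only_in_ramp_mode(self, tether, spec3, ou):
        tr_ramp, _ = ab.simulate_ramp_trace(spec3, ou, tether, None,
                                            duration=2.0, dt=1e-3, seed=1)
        tr_rel, _ = ab.simulate_relaxed_trace(spec3, ou, tether, duration=1.0, seed=1)
        assert tr_ramp.magnet_turns is not None and tr_ramp.mode == "ramp"
        assert tr_rel.magnet_turns is None and tr_rel.mode == "relaxed"


class TestCleavageGenerator:
    def test_zero_rate_gives_pure_noise_floor(self):
        tc = ab.simulate_cleavage_timecourse(0.8, 0.0, noise_sd=0.0, seed=0)
        np.testing.assert_array_equal(tc.fraction, 0.0)

    def test_saturation_reaches_amplitude(self):
        tc = ab.simulate_cleavage_timecourse(0.7, 5.0, times_min=(1.0, 10.0, 1e6),
                                             noise_sd=0.0, seed=0)
        assert tc.fraction[0, -1] == pytest.approx(0.7, abs=1e-9)

    def test_default_grid_and_replicates(self):
        tc = ab.simulate_cleavage_timecourse(0.8, 0.1, seed=0)
        np.testing.assert_array_equal(tc.times_min, DEFAULT_CLEAVAGE_TIMES_MIN)
        assert tc.n_reps == 3

    def test_fractions_clipped_to_unit_interval(self):
        tc = ab.simulate_cleavage_timecourse(1.0, 10.0, noise_sd=0.5, seed=0)
        assert tc.fraction.min() >= 0.0 and tc.fraction.max() <= 1.0

    @pytest.mark.parametrize("kwargs", [
        dict(A=0.0, kobs_per_min=1.0),
        dict(A=0.5, kobs_per_min=-1.0),
        dict(A=0.5, kobs_per_min=1.0, times_min=()),
        dict(A=0.5, kobs_per_min=1.0, noise_sd=-0.1),
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ab.simulate_cleavage_timecourse(**kwargs)
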