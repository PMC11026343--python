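import numpy as np
import pytest
from scipy.optimize import fsolve

import adloop as al
from adloop.neural import (JRGlobalParams, JRRegionalParams, NeuralRecording,
                           delays_from_lengths, equilibrium_state,
                           integrate_network, jr_derivatives, network_input,
                           regional_firing_rate, sigmoid)


class TestSigmoid:
    def test_half_activation_equals_e0(self):
        assert sigmoid(6.0) == pytest.approx(0.0025, abs=1e-15)

    def test_saturates_at_twice_e0(self):
        assert sigmoid(1e4) == pytest.approx(0.005, rel=1e-12)
        assert sigmoid(-1e4) == pytest.approx(0.0, abs=1e-12)

    def test_value_at_zero_matches_closed_form(self):
        # 2 e0 / (1 + exp(0.56 * 6)) evaluated at high precision
        assert sigmoid(0.0) == pytest.approx(1.67846116407413e-4, rel=1e-10)

    def test_monotone_increasing_with_bounded_range(self):
        v = np.linspace(-40, 40, 4001)
        s = sigmoid(v)
        assert np.all(np.diff(s) > 0)
        assert np.all((s > 0) & (s < 0.005))


class TestDelays:
    def test_forty_mm_at_twenty_mps_is_two_steps(self):
        ell = np.array([[0.0, 40.0], [40.0, 0.0]])
        assert delays_from_lengths(ell, s=20.0, dt_ms=1.0)[0, 1] == 2

    def test_zero_length_zero_steps(self):
        assert delays_from_lengths(np.zeros((2, 2)), 20.0, 1.0)[0, 1] == 0

    def test_matches_elementwise_rounding(self, rng):
        ell = rng.uniform(0, 200, (5, 5))
        d = delays_from_lengths(ell, s=7.5, dt_ms=0.5)
        ref = np.floor(ell / (7.5 * 0.5) + 0.5).astype(int)
        np.fill_diagonal(ref, 0)
        assert np.array_equal(d, ref)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            delays_from_lengths(np.array([[-1.0]]), 20.0, 1.0)


class TestNetworkInput:
    def test_decoupled_limit_returns_noise(self, rng):
        hist = rng.normal(0, 1, (10, 3))
        d = np.zeros((3, 3), dtype=int)
        w = rng.uniform(0, 1, (3, 3))
        out = network_input(1, 9, hist, w, d, g=0.0, noise_sample=0.17)
        assert out == pytest.approx(0.17)

    def test_two_nodes_at_half_activation(self):
        hist = np.full((5, 2), 6.0)  # v = v0 everywhere
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        d = np.ones((2, 2), dtype=int)
        out = network_input(0, 4, hist, w, d, g=25.0, noise_sample=0.0)
        assert out == pytest.approx(25.0 * 0.0025)

    def test_matches_brute_force_double_loop(self, rng):
        n, T = 5, 30
        hist = rng.normal(3, 4, (T, n))
        w = rng.uniform(0, 2, (n, n))
        d = rng.integers(0, 8, (n, n))
        for i in range(n):
            ref = 0.05 + 12.0 * sum(
                w[j, i] * sigmoid(hist[T - 1 - d[j, i], j])
                for j in range(n))
            got = network_input(i, T - 1, hist, w, d, g=12.0,
                                noise_sample=0.05)
            assert got == pytest.approx(ref, rel=1e-12)

    def test_prehistory_reads_initial_value(self):
        hist = np.vstack([np.full((1, 2), 2.0), np.full((4, 2), 9.0)])
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        d = np.full((2, 2), 10, dtype=int)  # lag beyond start
        out = network_input(0, 2, hist, w, d, g=1.0, noise_sample=0.0)
        assert out == pytest.approx(sigmoid(2.0))


class TestJRDerivatives:
    def test_zero_state_derivative_signs_and_values(self):
        glob, reg = JRGlobalParams(), JRRegionalParams()
        dy = jr_derivatives(np.zeros((6, 1)), np.zeros(1), glob, reg)
        # (Hi/tau_i) * Cip * S(0) and (He/tau_e) * S(0), frozen closed forms
        assert dy[5, 0] == pytest.approx(6.23128707162519e-3, rel=1e-10)
        assert dy[3, 0] == pytest.approx(5.45499878324091e-5, rel=1e-10)
        assert dy[5, 0] > 0 and dy[3, 0] > 0

    def test_equilibrium_from_root_finding_oracle(self):
        glob, reg = JRGlobalParams(), JRRegionalParams()

        def f(yflat):
            return jr_derivatives(yflat.reshape(6, 1),
                                  np.array([glob.p]), glob, reg).ravel()

        y0 = equilibrium_state(glob.p, glob, reg, branch="upper").ravel()
        root = fsolve(f, y0, full_output=False)
        assert np.all(np.abs(f(root)) < 1e-10)
        assert np.allclose(root, y0, atol=1e-6)

    def test_doubling_he_doubles_only_the_sigmoid_drive_terms(self, rng):
        glob = JRGlobalParams()
        y = rng.normal(0, 3, (6, 2))
        I = rng.uniform(0.05, 0.2, 2)
        d1 = jr_derivatives(y, I, glob, JRRegionalParams(He=3.25))
        d2 = jr_derivatives(y, I, glob, JRRegionalParams(He=6.5))
        decay3 = -(2 / glob.tau_e) * y[3] - y[0] / glob.tau_e**2
        # He scales the synaptic drive linearly; leak terms unchanged
        assert np.allclose(d2[3] - decay3, 2 * (d1[3] - decay3))
        assert np.allclose(d2[5], d1[5])
        assert np.allclose(d2[:3], d1[:3])


class TestIntegrateNetwork:
    def test_deterministic_given_seed(self, small_con):
        kw = dict(duration_ms=1500, discard_ms=500, rng_seed=4)
        a = integrate_network(small_con, **kw)
        b = integrate_network(small_con, **kw)
        assert np.array_equal(a.data, b.data)

    def test_duration_must_exceed_discard(self):
        with pytest.raises(ValueError):
            integrate_network(None, duration_ms=1000, discard_ms=1000)

    def test_decoupled_nodes_do_not_interact(self, small_con):
        glob0 = JRGlobalParams(g=0.0)
        a = integrate_network(small_con, glob0, duration_ms=1200,
                              discard_ms=200, rng_seed=9)
        he = np.full(small_con.n, 3.25)
        he[3] = 3.6  # perturb one region only
        b = integrate_network(small_con, glob0, JRRegionalParams(He=he),
                              duration_ms=1200, discard_ms=200, rng_seed=9)
        others = [i for i in range(small_con.n) if i != 3]
        assert np.array_equal(a.data[others], b.data[others])
        assert not np.array_equal(a.data[3], b.data[3])

    def test_noiseless_decoupled_run_settles_to_fixed_point(self):
        glob = JRGlobalParams(sigma=1e-300)
        rec = integrate_network(None, glob, duration_ms=6000,
                                discard_ms=4000, rng_seed=0)
        tail = rec.data[0, -500:]
        assert tail.std() < 1e-6

    def test_single_node_default_peaks_in_alpha(self):
        rec = integrate_network(None, duration_ms=20_000,
                                discard_ms=12_000, rng_seed=1)
        from adloop.metrics import spectral_peak
        assert 8.0 <= spectral_peak(rec, 0) <= 12.0

    def test_heun_close_to_fine_step_reference_when_noiseless(self):
        # transient relaxation onto the limit cycle, dt vs dt/10
        glob = JRGlobalParams(sigma=1e-300, p=0.15)
        coarse = integrate_network(None, glob, duration_ms=2000,
                                   discard_ms=0, dt_ms=1.0, rng_seed=0)
        fine = integrate_network(None, glob, duration_ms=2000,
                                 discard_ms=0, dt_ms=0.1, rng_seed=0)
        f = fine.data[0, ::10]
        c = coarse.data[0]
        err = np.linalg.norm(c - f) / np.linalg.norm(f)
        assert err < 0.05

    def test_lowering_cip_raises_single_node_firing_rate(self):
        rates = []
        for cip in [33.75, 27.0, 20.0, 13.25]:
            rec = integrate_network(None, regional=JRRegionalParams(Cip=cip),
                                    duration_ms=8000, discard_ms=4000,
                                    rng_seed=5)
            rates.append(regional_firing_rate(rec)[0])
        assert np.all(np.diff(rates) > 0)

    def test_blowup_aborts_with_diagnostic(self, small_con):
        glob = JRGlobalParams()
        glob.tau_e = 1e-4  # pathological stiffness forces divergence
        with pytest.raises(RuntimeError, match="blow-up|non-finite"):
            integrate_network(small_con, glob, duration_ms=2000,
                              discard_ms=100)


class TestRecordingAndRates:
    def test_firing_rate_of_constant_trace_at_v0(self):
        rec = NeuralRecording(data=np.full((2, 100), 6.0), dt_ms=1.0,
                              discard_ms=0.0)
        assert regional_firing_rate(rec) == pytest.approx([0.0025, 0.0025])

    def test_firing_rate_of_hyperpolarized_trace_vanishes(self):
        rec = NeuralRecording(data=np.full((1, 100), -1e4), dt_ms=1.0,
                              discard_ms=0.0)
        assert regional_firing_rate(rec)[0] == pytest.approx(0.0, abs=1e-12)

    def test_firing_rate_matches_pointwise_average(self, rng):
        saw = np.tile(np.linspace(-3, 12, 50), 4)[None, :]
        rec = NeuralRecording(data=saw, dt_ms=1.0, discard_ms=0.0)
        assert regional_firing_rate(rec)[0] == pytest.approx(
            sigmoid(saw).mean(), rel=1e-12)

    def test_empty_window_rejected(self):
        rec = NeuralRecording(data=np.empty((1, 0)), dt_ms=1.0,
                              discard_ms=0.0)
        with pytest.raises(ValueError):
            regional_firing_rate(rec)

    def test_save_load_round_trip(self, tmp_path):
        rec = NeuralRecording(data=np.random.default_rng(0).normal(
            0, 1, (3, 50)), dt_ms=0.5, discard_ms=100.0, meta={"g": 25.0})
        rec.save(tmp_path / "rec.txt")
        back = NeuralRecording.load(tmp_path / "rec.txt")
        assert np.allclose(back.data, rec.data)
        assert back.dt_ms == 0.5 and back.meta["g"] == 25.0
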