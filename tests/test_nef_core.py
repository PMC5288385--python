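"""Unit and property tests for the NEF core against independent oracles."""

import numpy as np
import pytest

from ratsearch import nef_core as nef


@pytest.fixture(scope="module")
def ens100():
    return nef.configure_ensemble(100, 1, seed=0)


def brute_force_lif_count(J, tau_rc, tau_ref, duration, dt=1e-5):
    """Forward-Euler integration of the LIF membrane ODE, counting spikes."""
    v, refr, count = 0.0, 0.0, 0
    steps = int(round(duration / dt))
    for _ in range(steps):
        if refr > 0:
            refr -= dt
            continue
        v += dt * (J - v) / tau_rc
        if v >= 1.0:
            count += 1
            v = 0.0
            refr = tau_ref
    return count


class TestLIFRate:
    def test_below_threshold_is_silent(self):
        assert nef.lif_rate(0.5, nef.LIFParams()) == 0.0
        assert nef.lif_rate(1.0, nef.LIFParams()) == 0.0

    def test_refractory_limit(self):
        p = nef.LIFParams(tau_ref=0.002)
        assert nef.lif_rate(1e12, p) == pytest.approx(500.0, rel=1e-3)

    def test_matches_brute_force_ode(self):
        p = nef.LIFParams()
        expected = nef.lif_rate(2.0, p)
        counted = brute_force_lif_count(2.0, p.tau_rc, p.tau_ref, duration=5.0)
        assert counted / 5.0 == pytest.approx(expected, rel=0.02)
        assert expected == pytest.approx(63.04, abs=0.1)

    def test_monotone_and_bounded(self):
        p = nef.LIFParams()
        J = np.linspace(0.0, 50.0, 400)
        r = nef.lif_rate(J, p)
        assert np.all(np.diff(r) >= 0)
        assert r.max() < 1.0 / p.tau_ref

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            nef.lif_rate(np.nan, nef.LIFParams())

    def test_rate_to_current_inverts(self):
        p = nef.LIFParams()
        rates = np.array([10.0, 100.0, 400.0])
        assert nef.lif_rate(nef.rate_to_current(rates, p), p) == pytest.approx(rates)


class TestLIFParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(tau_rc=-1.0), dict(tau_ref=-0.1), dict(dt=0.0), dict(dt=0.05)],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            nef.LIFParams(**kwargs)


class TestConfigureEnsemble:
    def test_tuning_contracts(self):
        rng = np.random.default_rng(3)
        ens = nef.configure_ensemble(50, 1, encoders="positive", rng=rng)
        p = ens.neuron_params
        # rate at e.x = 1 equals the sampled max rate; rate 0 at the intercept
        rates_at_one = nef.lif_rate(ens.gains + ens.biases, p)
        assert np.all(rates_at_one > 150.0)
        assert np.all(rates_at_one < 450.0)
        intercepts = (1.0 - ens.biases) / ens.gains
        at_intercept = ens.gains * intercepts + ens.biases
        assert at_intercept == pytest.approx(np.ones(50))

    def test_positive_encoders_give_monotone_curves(self):
        ens = nef.configure_ensemble(7, 1, encoders="positive", seed=1)
        x = np.linspace(0, 1, 50)[:, None]
        rates = ens.rates(x)
        assert np.all(np.diff(rates, axis=0) >= -1e-9)

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            nef.configure_ensemble(0, 1)

    def test_encoders_unit_norm(self):
        ens = nef.configure_ensemble(30, 8, seed=2)
        assert np.linalg.norm(ens.encoders, axis=1) == pytest.approx(np.ones(30))


class TestDecoders:
    def test_identity_rmse_vs_pseudoinverse_oracle(self, ens100):
        dec = nef.solve_decoders(ens100)
        X = np.linspace(-1, 1, 300)[:, None]
        A = ens100.rates(X)
        rmse = np.sqrt(np.mean((A @ dec.matrix - X) ** 2))
        assert rmse < 0.05
        # the unregularised pseudo-inverse solution bounds the fit from below
        d_oracle = np.linalg.pinv(A) @ X
        rmse_oracle = np.sqrt(np.mean((A @ d_oracle - X) ** 2))
        assert rmse_oracle <= rmse < rmse_oracle + 0.05

    def test_square_function_decodable(self, ens100):
        dec = nef.solve_decoders(ens100, function=lambda x: x**2)
        X = np.linspace(-1, 1, 300)[:, None]
        rmse = np.sqrt(np.mean((ens100.rates(X) @ dec.matrix - X**2) ** 2))
        assert rmse < 0.05

    def test_zero_target_gives_zero_decoders(self, ens100):
        dec = nef.solve_decoders(ens100, function=lambda x: 0.0 * x)
        assert np.allclose(dec.matrix, 0.0, atol=1e-9)

    def test_solution_is_local_optimum_of_regularised_error(self, ens100):
        dec = nef.solve_decoders(ens100, regularization=0.1)
        X = dec.eval_points
        A = ens100.rates(X)
        k = X.shape[0]
        sigma2 = (0.1 * A.max()) ** 2 * k

        def objective(d):
            return np.sum((A @ d - X) ** 2) + sigma2 * np.sum(d**2)

        base = objective(dec.matrix)
        rng = np.random.default_rng(11)
        scale = np.abs(dec.matrix).max()
        for _ in range(100):
            perturbed = dec.matrix + rng.normal(0, 0.01 * scale, dec.matrix.shape)
            assert objective(perturbed) >= base

    def test_unregularised_singular_solve_raises(self):
        # duplicate neurons make the activity Gram matrix exactly singular
        ens = nef.configure_ensemble(5, 1, encoders="positive", seed=4)
        ens2 = nef.Ensemble(
            10, 1,
            encoders=np.ones((10, 1)),
            gains=np.tile(ens.gains, 2),
            biases=np.tile(ens.biases, 2),
            neuron_params=ens.neuron_params,
        )
        with pytest.raises(nef.NEFError):
            nef.solve_decoders(ens2, regularization=0.0)


class TestSpikingDynamics:
    def test_zero_input_never_spikes(self):
        ens = nef.Ensemble(3, 1, np.ones((3, 1)), np.ones(3), np.zeros(3))
        for _ in range(1000):
            assert nef.step_lif(ens, np.zeros(3), 0.001).sum() == 0

    @pytest.mark.parametrize("J", [1.5, 2.0, 8.0])
    def test_spike_count_matches_closed_form_rate(self, J):
        p = nef.LIFParams()
        ens = nef.Ensemble(1, 1, np.ones((1, 1)), np.array([1.0]), np.array([0.0]))
        count = sum(
            nef.step_lif(ens, np.array([J]), p.dt)[0] for _ in range(10000)
        )
        assert count / 10.0 == pytest.approx(nef.lif_rate(J, p), rel=0.02)

    def test_interspike_interval_matches_rate(self):
        p = nef.LIFParams()
        ens = nef.Ensemble(1, 1, np.ones((1, 1)), np.array([1.0]), np.array([0.0]))
        spike_steps = [
            t for t in range(2000)
            if nef.step_lif(ens, np.array([2.0]), p.dt)[0] > 0
        ]
        isis = np.diff(spike_steps) * p.dt
        assert np.all(np.abs(isis - 1.0 / nef.lif_rate(2.0, p)) <= p.dt)

    def test_no_spike_during_refractory(self):
        ens = nef.Ensemble(1, 1, np.ones((1, 1)), np.array([1.0]), np.array([0.0]))
        ens.refractory_time[:] = 0.010
        for _ in range(8):  # well inside the forced refractory window
            assert nef.step_lif(ens, np.array([1e6]), 0.001)[0] == 0

    def test_voltage_stays_normalised(self):
        ens = nef.configure_ensemble(20, 1, seed=5)
        rng = np.random.default_rng(0)
        for _ in range(500):
            nef.step_lif(ens, rng.normal(0, 5, 20), 0.001)
            assert np.all(ens.voltage >= 0.0)
            assert np.all(ens.voltage <= 1.0)


class TestFilterDecode:
    def test_no_spikes_decodes_zero(self, ens100):
        dec = nef.solve_decoders(ens100)
        out = nef.filter_decode(
            np.zeros((100, 100)), dec, nef.SynapticFilter(0.005), 0.001
        )
        assert np.allclose(out, 0.0)

    def test_constant_value_reconstructed(self, ens100):
        dec = nef.solve_decoders(ens100)
        ens100.reset_state()
        J = ens100.currents(np.array([0.8]))
        spikes = np.array([nef.step_lif(ens100, J, 0.001) for _ in range(600)])
        xhat = nef.filter_decode(spikes, dec, nef.SynapticFilter(0.02), 0.001)
        assert xhat[200:].mean() == pytest.approx(0.8, abs=0.05)

    def test_impulse_response_has_decoder_area(self):
        dec = nef.Decoders(matrix=np.array([[0.37]]))
        spikes = np.zeros((2000, 1))
        spikes[10, 0] = 1.0
        out = nef.filter_decode(spikes, dec, nef.SynapticFilter(0.005), 0.001)
        assert out.sum() * 0.001 == pytest.approx(0.37, rel=1e-3)

    def test_mismatched_lengths_rejected(self):
        dec = nef.Decoders(matrix=np.zeros((5, 1)))
        with pytest.raises(ValueError):
            nef.filter_decode(np.zeros((10, 3)), dec, nef.SynapticFilter(0.005), 0.001)

    def test_kernel_normalised(self):
        kernel = nef.SynapticFilter(0.005).kernel(dt=0.001)
        assert kernel.sum() == pytest.approx(1.0, abs=1e-6)


class TestConnections:
    def test_factored_weights_equal_full_matrix_currents(self):
        pre = nef.configure_ensemble(5, 1, seed=3)
        post = nef.configure_ensemble(5, 1, seed=4)
        conn = nef.connect(pre, post)
        W = conn.full_weight_matrix()
        for x in (-0.7, 0.0, 0.37, 1.0):
            acts = pre.rates(np.array([x]))
            decoded = acts @ conn.decoders.matrix
            j_factored = post.gains * (post.encoders @ decoded) + post.biases
            j_full = W @ acts + post.biases
            assert np.allclose(j_factored, j_full, atol=1e-12)

    def test_zero_transform_leaves_only_bias_currents(self):
        pre = nef.configure_ensemble(20, 1, seed=6)
        post = nef.configure_ensemble(20, 1, seed=7)
        conn = nef.connect(pre, post, transform=np.zeros((1, 1)))
        assert np.allclose(conn.full_weight_matrix(), 0.0)

    def test_dimension_mismatch_rejected(self):
        pre = nef.configure_ensemble(10, 2, seed=8)
        post = nef.configure_ensemble(10, 3, seed=9)
        with pytest.raises(ValueError):
            nef.connect(pre, post)

    def test_communication_channel_chain(self):
        net = nef.Network()
        inp = net.add_node(nef.Node(0.5))
        a = net.add_ensemble(nef.configure_ensemble(100, 1, seed=1))
        b = net.add_ensemble(nef.configure_ensemble(100, 1, seed=2))
        net.connect(inp, a, synapse=None)
        net.connect(a, b)
        probe = net.probe(b, synapse=nef.SynapticFilter(0.02))
        sim = nef.Simulator(net)
        sim.run(0.5)
        decoded = sim.probe_data(probe)
        assert decoded[300:].mean() == pytest.approx(0.5, abs=0.07)


class TestAlphaRateEstimate:
    def test_empty_train_gives_zero(self):
        assert np.allclose(nef.alpha_rate_estimate(np.zeros(500), alpha=50.0), 0.0)

    def test_single_spike_peaks_one_over_alpha_later(self):
        spikes = np.zeros(2000)
        spikes[100] = 1.0
        trace = nef.alpha_rate_estimate(spikes, alpha=50.0, dt=0.001)
        peak = np.argmax(trace)
        assert (peak - 100) * 0.001 == pytest.approx(1.0 / 50.0, abs=0.002)

    def test_regular_train_plateaus_at_rate(self):
        spikes = np.zeros(5000)
        spikes[::10] = 1.0  # 100 Hz at 1 ms steps
        trace = nef.alpha_rate_estimate(spikes, alpha=50.0, dt=0.001)
        assert abs(trace[2000:4000].mean() - 100.0) <= 5.0

    def test_rejects_nonpositive_alpha(self):
        with pytest.raises(ValueError):
            nef.alpha_rate_estimate(np.zeros(10), alpha=0.0)
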