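"""Plateau potentials, DEP weight updates, and the two-phase trial."""

import numpy as np
import pytest

from dendep.data import LabeledImage, generate_oriented_bars
from dendep.dynamics import NetworkConfig
from dendep.learning import (
    LearningConfig,
    PhaseRecord,
    PlateauSet,
    SynapseSet,
    compute_plateau,
    coupling_factor_kb,
    hidden_update,
    output_update,
    run_two_phase_trial,
    sample_interphase_interval,
    target_rate,
)
from dendep.pwl import dsigmoid, sigmoid


def _phase_record(cfg, s_input, v_hidden, v_output=None, rate_out_f=None,
                  rate_out_t=None, s_hidden=None, apical=None):
    """PhaseRecord with hand-set averages (single hidden layer)."""
    n_h = cfg.hidden_sizes[0] if cfg.hidden_sizes else 0
    p = cfg.n_output
    zeros_h = np.zeros(n_h)
    return PhaseRecord(
        t0=0.0, t1=80.0, t2=160.0, dt1=50.0, dt2=50.0,
        apical_f=[apical if apical is not None else zeros_h.copy()],
        apical_t=[zeros_h.copy()],
        v_hidden_f=[np.asarray(v_hidden)],
        s_input_f=np.asarray(s_input),
        s_hidden_f=[s_hidden if s_hidden is not None else zeros_h.copy()],
        rate_hidden_f=[cfg.phi_max * sigmoid(np.asarray(v_hidden))],
        v_output_f=(np.asarray(v_output) if v_output is not None
                    else np.zeros(p)),
        rate_output_f=(np.asarray(rate_out_f) if rate_out_f is not None
                       else np.full(p, 0.1)),
        rate_output_t=(np.asarray(rate_out_t) if rate_out_t is not None
                       else np.full(p, 0.1)),
    )


@pytest.fixture
def toy_cfg():
    return NetworkConfig(n_input=4, hidden_sizes=(3,), n_output=2)


class TestPlateaus:
    def test_constant_zero_trace_gives_half(self):
        trace = np.zeros((40, 5))
        np.testing.assert_allclose(compute_plateau(trace, (10, 40)), 0.5)

    def test_constant_trace_gives_sigmoid(self):
        trace = np.full((30, 2), 1.7)
        np.testing.assert_allclose(compute_plateau(trace, (0, 30)),
                                   sigmoid(1.7))

    def test_time_varying_trace_matches_direct_mean(self):
        rng = np.random.default_rng(0)
        trace = rng.normal(0, 1, (100, 4))
        got = compute_plateau(trace, (20, 90))
        np.testing.assert_allclose(got, sigmoid(trace[20:90].mean(axis=0)))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            compute_plateau(np.zeros((10, 2)), (5, 5))

    def test_plateau_set_range_enforced(self):
        with pytest.raises(ValueError):
            PlateauSet(np.array([0.5]), np.array([1.0]))


class TestScalarPieces:
    def test_kb_examples(self):
        assert coupling_factor_kb(1, 1, 1) == pytest.approx(1 / 3)
        assert coupling_factor_kb(0.5, 2.0, 0.0) == pytest.approx(0.8)
        with pytest.raises(ValueError):
            coupling_factor_kb(0, 0, 0)

    def test_target_rate_identity_when_plateaus_equal(self):
        phi = np.array([0.1, 0.12])
        a = np.array([0.4, 0.6])
        np.testing.assert_allclose(target_rate(phi, a, a), phi, atol=1e-15)

    def test_target_rate_offset(self):
        phi = np.array([0.1])
        got = target_rate(phi, np.array([0.55]), np.array([0.45]))
        assert got[0] == pytest.approx(0.2)


class TestHiddenUpdate:
    def test_zero_when_plateaus_equal(self, toy_cfg):
        rng = np.random.default_rng(0)
        syn = SynapseSet.initialize(toy_cfg, rng)
        phase = _phase_record(toy_cfg, rng.uniform(0, 0.2, 4),
                              rng.normal(0, 1, 3))
        alpha = np.full(3, 0.5)
        dW, db = hidden_update(phase, PlateauSet(alpha, alpha), syn,
                               toy_cfg, LearningConfig())
        np.testing.assert_array_equal(dW, 0.0)
        np.testing.assert_array_equal(db, 0.0)

    def test_positive_credit_raises_active_synapses(self, toy_cfg):
        """A positive plateau difference with a positive presynaptic trace
        must increase the basal drive (gradient descent direction)."""
        rng = np.random.default_rng(1)
        syn = SynapseSet.initialize(toy_cfg, rng)
        s = np.array([0.2, 0.0, 0.1, 0.0])
        phase = _phase_record(toy_cfg, s, np.zeros(3))
        pl = PlateauSet(np.full(3, 0.5), np.full(3, 0.6))  # α_t > α_f
        dW, db = hidden_update(phase, pl, syn, toy_cfg, LearningConfig())
        assert np.all(dW[:, s > 0] > 0)
        np.testing.assert_array_equal(dW[:, s == 0], 0.0)
        assert np.all(db > 0)

    def test_matches_finite_difference_gradient(self, toy_cfg):
        """The update must descend L0 = ||φ0* − Φ_max σ(V̄0f)||² with the
        target held fixed: compare against a central finite-difference
        gradient through the soma fixed point, elementwise to 1e-4
        relative (up to the constant-2 factor absorbed into η·P)."""
        cfg = toy_cfg
        rng = np.random.default_rng(7)
        W0 = rng.normal(0, 0.3, (3, 4))
        b0 = rng.normal(0, 0.1, 3)
        s_in = rng.uniform(0.05, 0.2, 4)
        v0a = rng.normal(0, 0.2, 3)
        phi_star = rng.uniform(0.05, 0.15, 3)
        kb = coupling_factor_kb(cfg.g_l, cfg.g_b, cfg.g_a)
        ka = cfg.g_a / (cfg.g_l + cfg.g_b + cfg.g_a)

        def forward_rate(W, b):
            v0f = kb * (W @ s_in + b) + ka * v0a
            return cfg.phi_max * sigmoid(v0f), v0f

        rate_f, v0f = forward_rate(W0, b0)

        def loss(W, b):
            r, _ = forward_rate(W, b)
            return float(np.sum((phi_star - r) ** 2))

        eps = 1e-6
        fd_grad_W = np.zeros_like(W0)
        for idx in np.ndindex(W0.shape):
            Wp, Wm = W0.copy(), W0.copy()
            Wp[idx] += eps
            Wm[idx] -= eps
            fd_grad_W[idx] = (loss(Wp, b0) - loss(Wm, b0)) / (2 * eps)
        fd_grad_b = np.zeros_like(b0)
        for i in range(3):
            bp, bm = b0.copy(), b0.copy()
            bp[i] += eps
            bm[i] -= eps
            fd_grad_b[i] = (loss(W0, bp) - loss(W0, bm)) / (2 * eps)

        # encode the same state in a PhaseRecord/PlateauSet: the credit
        # signal α_t − α_f equals φ0* − Φ̄0f
        syn = SynapseSet([W0, rng.normal(0, 0.1, (2, 3))],
                         [b0, np.zeros(2)], [rng.uniform(-1, 1, (3, 2))])
        phase = _phase_record(cfg, s_in, v0f)
        alpha_f = np.full(3, 0.5)
        pl = PlateauSet(alpha_f, alpha_f + (phi_star - rate_f))
        lcfg = LearningConfig(eta_hidden=1.0, p_hidden=1.0)
        dW, db = hidden_update(phase, pl, syn, cfg, lcfg)

        # update = −(η·P/2) · ∇L0 exactly; FD introduces O(eps²) error
        np.testing.assert_allclose(dW, -0.5 * fd_grad_W, rtol=1e-4)
        np.testing.assert_allclose(db, -0.5 * fd_grad_b, rtol=1e-4)

    def test_hand_computed_oracle_three_neurons(self, toy_cfg):
        """Update equals the analytic expression computed with plain
        Python loops on a 3-neuron toy network."""
        cfg = toy_cfg
        s = [0.1, 0.2, 0.0, 0.05]
        v0f = [0.3, -0.2, 0.0]
        af, at = [0.45, 0.55, 0.5], [0.5, 0.5, 0.58]
        syn = SynapseSet([np.zeros((3, 4)), np.zeros((2, 3))],
                         [np.zeros(3), np.zeros(2)], [np.zeros((3, 2))])
        phase = _phase_record(cfg, np.array(s), np.array(v0f))
        pl = PlateauSet(np.array(af), np.array(at))
        lcfg = LearningConfig(eta_hidden=2.0, p_hidden=3.0)
        dW, db = hidden_update(phase, pl, syn, cfg, lcfg)
        kb = cfg.g_b / (cfg.g_l + cfg.g_b + cfg.g_a)
        for i in range(3):
            sig = 1 / (1 + np.exp(-v0f[i]))
            d_i = kb * (at[i] - af[i]) * cfg.phi_max * sig * (1 - sig)
            assert db[i] == pytest.approx(2.0 * 3.0 * d_i, rel=1e-12)
            for j in range(4):
                assert dW[i, j] == pytest.approx(2.0 * 3.0 * d_i * s[j],
                                                 rel=1e-12)


class TestOutputUpdate:
    def test_zero_when_target_equals_forward(self, toy_cfg):
        rng = np.random.default_rng(2)
        syn = SynapseSet.initialize(toy_cfg, rng)
        r = np.array([0.08, 0.11])
        phase = _phase_record(toy_cfg, np.zeros(4), np.zeros(3),
                              rate_out_f=r, rate_out_t=r.copy(),
                              s_hidden=np.full(3, 0.1))
        dW, db = output_update(phase, syn, toy_cfg, LearningConfig())
        np.testing.assert_array_equal(dW, 0.0)
        np.testing.assert_array_equal(db, 0.0)

    def test_direction_matches_finite_difference(self):
        """Delta rule direction = gradient of the output loss on a 2x2
        toy network (normalized comparison; constant factors are
        absorbed into η1)."""
        cfg = NetworkConfig(n_input=2, hidden_sizes=(2,), n_output=2)
        rng = np.random.default_rng(3)
        W1 = rng.normal(0, 0.5, (2, 2))
        b1 = rng.normal(0, 0.1, 2)
        s0 = rng.uniform(0.05, 0.2, 2)
        target = rng.uniform(0.02, 0.18, 2)
        kd = cfg.g_d / (cfg.g_l + cfg.g_d)

        def fwd(W, b):
            v1f = kd * (W @ s0 + b)
            return cfg.phi_max * sigmoid(v1f), v1f

        rate_f, v1f = fwd(W1, b1)

        def loss(W, b):
            r, _ = fwd(W, b)
            return float(np.sum((target - r) ** 2))

        eps = 1e-6
        fd = np.zeros_like(W1)
        for idx in np.ndindex(W1.shape):
            Wp, Wm = W1.copy(), W1.copy()
            Wp[idx] += eps
            Wm[idx] -= eps
            fd[idx] = (loss(Wp, b1) - loss(Wm, b1)) / (2 * eps)

        syn = SynapseSet([rng.normal(size=(2, 2)), W1],
                         [np.zeros(2), b1], [rng.uniform(-1, 1, (2, 2))])
        phase = _phase_record(cfg, np.zeros(2), np.zeros(2), v_output=v1f,
                              rate_out_f=rate_f, rate_out_t=target,
                              s_hidden=s0)
        dW, _ = output_update(phase, syn, cfg, LearningConfig(eta_output=1.0))
        a = dW.ravel() / np.linalg.norm(dW)
        b = -fd.ravel() / np.linalg.norm(fd)
        np.testing.assert_allclose(a, b, atol=1e-6)


class TestInterphaseInterval:
    def test_positive_and_reproducible(self):
        rng = np.random.default_rng(0)
        draws = [sample_interphase_interval(rng, 50.0, 500.0)
                 for _ in range(1000)]
        assert min(draws) > 0
        again = np.random.default_rng(0)
        assert sample_interphase_interval(again, 50.0, 500.0) == draws[0]

    def test_empirical_mean(self):
        rng = np.random.default_rng(1)
        n = 100_000
        draws = rng.wald(50.0, 500.0, size=n)
        se = draws.std() / np.sqrt(n)
        assert abs(draws.mean() - 50.0) < 3 * se

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            sample_interphase_interval(np.random.default_rng(0), -1.0, 1.0)


class TestTwoPhaseTrial:
    @pytest.fixture
    def small_cfg(self):
        return NetworkConfig(n_input=81, hidden_sizes=(20,), n_output=8,
                             ipi_mean=40.0, ipi_shape=400.0)

    def test_feedback_weights_never_change(self, small_cfg):
        rng = np.random.default_rng(0)
        syn = SynapseSet.initialize(small_cfg, rng)
        y_before = syn.Y.copy()
        ds = generate_oriented_bars(1, size=9, seed=0)
        for img in ds:
            run_two_phase_trial(img, syn, small_cfg, LearningConfig(), rng)
        np.testing.assert_array_equal(syn.Y, y_before)

    def test_zero_image_produces_no_input_spikes(self, small_cfg):
        rng = np.random.default_rng(1)
        syn = SynapseSet.initialize(small_cfg, rng)
        img = LabeledImage(np.zeros((9, 9)), 0)
        log = run_two_phase_trial(img, syn, small_cfg, LearningConfig(), rng)
        assert log.spike_counts["input"] == 0

    def test_phase_time_bookkeeping(self, small_cfg):
        rng = np.random.default_rng(2)
        syn = SynapseSet.initialize(small_cfg, rng)
        img = generate_oriented_bars(1, size=9, seed=1)[0]
        log = run_two_phase_trial(img, syn, small_cfg, LearningConfig(), rng)
        ph = log.phase
        assert ph.t0 < ph.t1 < ph.t2
        assert ph.dt1 == pytest.approx(ph.t1 - (ph.t0 + small_cfg.settle_ms))
        assert ph.dt2 == pytest.approx(ph.t2 - (ph.t1 + small_cfg.settle_ms))
        assert ph.dt1 >= small_cfg.settle_ms

    def test_trial_determinism(self, small_cfg):
        ds = generate_oriented_bars(1, size=9, seed=3)
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(11)
            syn = SynapseSet.initialize(small_cfg, rng)
            for img in ds:
                log = run_two_phase_trial(img, syn, small_cfg,
                                          LearningConfig(), rng)
            outs.append((syn.W0.copy(), log.synops, log.loss))
        np.testing.assert_array_equal(outs[0][0], outs[1][0])
        assert outs[0][1:] == outs[1][1:]

    def test_loss_proxy_decreases_with_training(self, small_cfg):
        """Mean ||α_t − α_f||² shrinks across epochs on a tiny task."""
        rng = np.random.default_rng(5)
        syn = SynapseSet.initialize(small_cfg, rng)
        ds = generate_oriented_bars(4, size=9, seed=5)
        epoch_losses = []
        for _ in range(4):
            total = 0.0
            for img in ds:
                total += run_two_phase_trial(img, syn, small_cfg,
                                             LearningConfig(), rng).loss
            epoch_losses.append(total / len(ds))
        assert epoch_losses[-1] < epoch_losses[0]

    def test_quantized_mode_keeps_weights_representable(self, small_cfg):
        from dendep.quantization import dynamic_quantize
        rng = np.random.default_rng(6)
        syn = SynapseSet.initialize(small_cfg, rng)
        lcfg = LearningConfig(weight_mode="dynamic", dynamic_bits=16)
        img = generate_oriented_bars(1, size=9, seed=6)[0]
        run_two_phase_trial(img, syn, small_cfg, lcfg, rng)
        redec = dynamic_quantize(syn.W0, 16, lcfg.r_max).decode()
        np.testing.assert_array_equal(syn.W0, redec)

    def test_pwl_and_binarized_modes_run(self, small_cfg):
        rng = np.random.default_rng(7)
        syn = SynapseSet.initialize(small_cfg, rng)
        lcfg = LearningConfig(sigmoid_mode="pwl", binarize_traces=True)
        img = generate_oriented_bars(1, size=9, seed=7)[0]
        log = run_two_phase_trial(img, syn, small_cfg, lcfg, rng)
        assert np.isfinite(log.loss)

    def test_no_hidden_layer_trial(self):
        cfg = NetworkConfig(n_input=81, hidden_sizes=(), n_output=8)
        rng = np.random.default_rng(8)
        syn = SynapseSet.initialize(cfg, rng)
        img = generate_oriented_bars(1, size=9, seed=8)[0]
        log = run_two_phase_trial(img, syn, cfg, LearningConfig(), rng)
        assert log.loss == 0.0  # no plateaus without a hidden layer
        assert log.plateaus == []

    def test_jsonl_log_round_trip(self, small_cfg, tmp_path):
        import json
        rng = np.random.default_rng(9)
        syn = SynapseSet.initialize(small_cfg, rng)
        img = generate_oriented_bars(1, size=9, seed=9)[0]
        log = run_two_phase_trial(img, syn, small_cfg, LearningConfig(), rng)
        rec = json.loads(log.to_json())
        assert rec["label"] == img.label
        assert rec["synops"] == log.synops
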