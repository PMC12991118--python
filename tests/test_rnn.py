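"""Rate-RNN plasticity-locus models: dynamics, BPTT, in-silico photostim."""

import numpy as np
import pytest

from photoplast import rnn
from photoplast.rnn import RNNConfig


def tiny_cfg(**kw):
    base = dict(n=8, d=3, noise_scale=0.0, pretrial_steps=20, late_steps=20)
    base.update(kw)
    return RNNConfig(**base)


def prepared(cfg, seed=0):
    model = rnn.init_model(cfg, seed)
    stab = rnn.run_stabilization(model, np.random.default_rng(seed + 1), 4)
    cn, gh = rnn.select_model_cn(model, stab)
    rnn.attach_feedback(model, cn, gh, seed + 2)
    return model


class TestDynamics:
    def test_zero_everything_is_fixed_point(self):
        cfg = tiny_cfg()
        model = rnn.init_model(cfg, 0)
        model.W_rec[:] = 0
        model.W_inp[:] = 0
        h = rnn.step_dynamics(model, np.zeros(cfg.n), np.zeros(cfg.d))
        np.testing.assert_allclose(h, 0.0)

    def test_linear_two_neuron_matches_closed_form(self):
        """With linear phi and no noise the map is affine; compare to the
        matrix-power recursion computed independently."""
        cfg = RNNConfig(n=2, d=1, noise_scale=0.0, nonlinearity="linear",
                        pretrial_steps=5, late_steps=5)
        model = rnn.init_model(cfg, 1)
        W, B = model.W_rec, model.W_inp
        a = cfg.alpha
        x = np.array([0.7])
        A = (1 - a) * np.eye(2) + a * W
        b = a * (B @ x)
        h_direct = np.zeros(2)
        for _ in range(7):
            h_direct = rnn.step_dynamics(model, h_direct, x)
        h_closed = np.zeros(2)
        for _ in range(7):
            h_closed = A @ h_closed + b
        np.testing.assert_allclose(h_direct, h_closed, rtol=1e-12)

    def test_same_seed_same_trajectory(self):
        cfg = tiny_cfg(noise_scale=0.05)
        model = rnn.init_model(cfg, 2)
        H1, _ = rnn.simulate_trial(model, np.random.default_rng(42))
        H2, _ = rnn.simulate_trial(model, np.random.default_rng(42))
        np.testing.assert_array_equal(H1, H2)

    def test_nonfinite_state_rejected(self):
        cfg = tiny_cfg()
        model = rnn.init_model(cfg, 0)
        with pytest.raises(FloatingPointError):
            rnn.step_dynamics(model, np.full(cfg.n, np.inf), np.zeros(cfg.d))


class TestCNSelection:
    def test_dominating_neuron_selected(self):
        cfg = tiny_cfg()
        model = rnn.init_model(cfg, 0)
        stab = np.zeros((2, cfg.trial_steps + 1, cfg.n))
        stab[:, :, 3] = 1.0  # neuron 3 high and flat in both periods
        stab[:, 1: cfg.pretrial_steps + 1, 5] = 0.9
        stab[:, cfg.pretrial_steps + 1:, 5] = 0.2
        cn, gamma = rnn.select_model_cn(model, stab)
        assert cn == 3
        assert gamma == pytest.approx(1.0)

    def test_matches_brute_force_filter(self):
        cfg = RNNConfig(n=100, d=10, noise_scale=0.01)
        model = rnn.init_model(cfg, 3)
        stab = rnn.run_stabilization(model, np.random.default_rng(4), 5)
        cn, _ = rnn.select_model_cn(model, stab)
        pre = stab[:, 1: cfg.pretrial_steps + 1].mean(axis=(0, 1))
        late = stab[:, cfg.pretrial_steps + 1:].mean(axis=(0, 1))
        best, best_gap = None, np.inf
        for i in range(cfg.n):
            if pre[i] > np.median(pre) and late[i] > np.median(late):
                gap = abs(pre[i] - late[i])
                if gap < best_gap:
                    best, best_gap = i, gap
        assert cn == best

    def test_feedback_constraint_exact(self):
        for seed in range(20):
            model = prepared(tiny_cfg(noise_scale=0.01), seed)
            assert float(model.w_back @ model.w_bci) == 1.0


class TestTraining:
    def test_bptt_gradients_match_finite_differences(self):
        cfg = tiny_cfg(plasticity_locus="both")
        model = prepared(cfg, 0)
        H, cache = rnn.simulate_trial(model, np.random.default_rng(5), record=True)
        # exact check requires aligned feedback (w_back carries the credit)
        model.w_back = model.w_bci.copy()
        loss, grads = rnn._backward_trial(model, H, cache)
        eps = 1e-6
        for name in ("W_rec", "W_inp"):
            W = getattr(model, name)
            for (i, j) in [(0, 1), (3, 2)]:
                W[i, j] += eps
                H2, _ = rnn.simulate_trial(model, np.random.default_rng(5),
                                           record=True)
                l2 = float(np.mean(
                    (H2[cfg.pretrial_steps + 1:, model.cn] - model.gamma_hat) ** 2
                ))
                W[i, j] -= eps
                num = (l2 - loss) / eps
                assert grads[name][i, j] == pytest.approx(num, rel=1e-3, abs=1e-9)

    def test_zero_lr_changes_nothing(self):
        model = prepared(tiny_cfg(noise_scale=0.01, plasticity_locus="recurrent"), 1)
        w0 = model.W_rec.copy()
        log = rnn.train_bptt(model, 5, 0.0, np.random.default_rng(6))
        np.testing.assert_array_equal(model.W_rec, w0)

    @pytest.mark.parametrize(
        "locus, frozen",
        [
            ("recurrent", ("W_inp", "a_exc")),
            ("input", ("W_rec", "a_exc")),
            ("excitability", ("W_rec", "W_inp")),
        ],
    )
    def test_locus_isolation_bit_identical(self, locus, frozen):
        model = prepared(tiny_cfg(noise_scale=0.01, plasticity_locus=locus), 2)
        before = {name: getattr(model, name).copy() for name in frozen}
        trained = {"recurrent": "W_rec", "input": "W_inp",
                   "excitability": "a_exc"}[locus]
        w_trained = getattr(model, trained).copy()
        rnn.train_bptt(model, 8, 0.5, np.random.default_rng(7))
        for name in frozen:
            np.testing.assert_array_equal(getattr(model, name), before[name])
        assert not np.array_equal(getattr(model, trained), w_trained)

    def test_upstream_locus_trains_only_upstream_recurrent(self):
        cfg = tiny_cfg(noise_scale=0.01, plasticity_locus="upstream_recurrent")
        model = prepared(cfg, 3)
        frozen = {n: getattr(model, n).copy()
                  for n in ("W_rec", "W_inp", "W_inp_up", "W_inp_up_in")}
        w_up = model.W_rec_up.copy()
        rnn.train_bptt(model, 8, 0.5, np.random.default_rng(8))
        for n, w in frozen.items():
            np.testing.assert_array_equal(getattr(model, n), w)
        assert not np.array_equal(model.W_rec_up, w_up)

    def test_deterministic_with_zero_noise(self):
        logs = []
        for _ in range(2):
            model = prepared(tiny_cfg(plasticity_locus="recurrent"), 4)
            log = rnn.train_bptt(model, 6, 0.1, np.random.default_rng(9))
            logs.append(log.loss)
        np.testing.assert_array_equal(logs[0], logs[1])

    def test_both_locus_matches_layer_change_magnitudes(self):
        cfg = RNNConfig(plasticity_locus="both", n=50, d=10)
        model = prepared(cfg, 5)
        log = rnn.train_bptt(model, 15, 0.1, np.random.default_rng(10))
        norms = log.layer_change_norms
        ratio = norms["W_rec"] / norms["W_inp"]
        assert 0.2 < ratio < 5.0

    def test_rejection_flag_on_nondecreasing_loss(self):
        # zero noise, zero lr: loss is identical every trial -> flagged
        model = prepared(tiny_cfg(noise_scale=0.0), 6)
        log = rnn.train_bptt(model, 10, 0.0, np.random.default_rng(11))
        assert log.rejected


class TestPhotostim:
    def test_decoupled_network_no_offtarget_response(self):
        cfg = tiny_cfg(noise_scale=0.01)
        model = rnn.init_model(cfg, 7)
        model.W_rec[:] = 0.0
        W = rnn.insilico_photostim(model, h_pert=1.0, repeats=5,
                                   rng=np.random.default_rng(12))
        off = W[~np.isnan(W)]
        assert np.abs(off).max() < 0.05

    def test_linear_propagator_oracle(self):
        """Zero noise, linear phi: clamp response equals the steady-state
        solution of (I - W) h = W e_g * h_pert on the unclamped block."""
        cfg = RNNConfig(n=5, d=2, noise_scale=0.0, nonlinearity="linear",
                        w_rec_scale=0.4)
        model = rnn.init_model(cfg, 8)
        h_pert = 0.3
        W = rnn.insilico_photostim(model, h_pert=h_pert, repeats=1,
                                   rng=np.random.default_rng(0),
                                   before_steps=50, clamp_steps=600,
                                   clamp_settle=400)
        Wr = model.W_rec
        for g in range(5):
            others = [i for i in range(5) if i != g]
            A = np.eye(4) - Wr[np.ix_(others, others)]
            b = Wr[others, g] * h_pert
            h_ss = np.linalg.solve(A, b)
            np.testing.assert_allclose(W[others, g], h_ss, rtol=1e-3, atol=1e-9)

    def test_more_repeats_reduce_variance(self):
        cfg = tiny_cfg(noise_scale=0.05)
        model = rnn.init_model(cfg, 9)
        est = {}
        for reps in (1, 5):
            maps = [
                rnn.insilico_photostim(model, repeats=reps,
                                       rng=np.random.default_rng(100 + k))
                for k in range(6)
            ]
            with np.errstate(invalid="ignore"):
                est[reps] = np.nanmean(np.nanstd(np.stack(maps), axis=0))
        assert est[5] < est[1]

    def test_out_of_range_group_rejected(self):
        model = rnn.init_model(tiny_cfg(), 10)
        with pytest.raises(IndexError):
            rnn.insilico_photostim(model, groups=np.array([99]))


class TestLoopInputRatio:
    def _loop_model(self):
        cfg = tiny_cfg(w_csc_scale=0.2)
        return rnn.init_model(cfg, 11)

    def test_zero_loop_weights_zero_ratio(self):
        model = self._loop_model()
        model.W_csc[:] = 0.0
        H = np.random.default_rng(0).normal(size=(10, model.cfg.n))
        X = np.ones((10, model.cfg.d))
        assert rnn.loop_input_ratio(model, H, X) == 0.0

    def test_homogeneity(self):
        model = self._loop_model()
        H = np.random.default_rng(1).normal(size=(10, model.cfg.n))
        X = np.random.default_rng(2).normal(size=(10, model.cfg.d))
        r1 = rnn.loop_input_ratio(model, H, X)
        model.W_csc *= 2.0
        assert rnn.loop_input_ratio(model, H, X) == pytest.approx(2 * r1)

    def test_three_step_hand_computation(self):
        model = self._loop_model()
        H = np.ones((3, model.cfg.n))
        X = np.ones((3, model.cfg.d))
        num = 3 * np.linalg.norm(model.W_csc @ np.ones(model.cfg.n))
        den = 3 * np.linalg.norm(np.ones(model.cfg.d))
        assert rnn.loop_input_ratio(model, H, X) == pytest.approx(num / den)

    def test_zero_task_input_rejected(self):
        model = self._loop_model()
        H = np.ones((3, model.cfg.n))
        with pytest.raises(ValueError):
            rnn.loop_input_ratio(model, H, np.zeros((3, model.cfg.d)))


class TestRejectionBookkeeping:
    @pytest.mark.parametrize("locus", ["excitability", "upstream_recurrent"])
    def test_noisy_variants_report_rejection_fraction(self, locus):
        res = rnn.run_locus_experiment(
            locus, seeds=range(3), cfg=RNNConfig(plasticity_locus=locus),
            lr=0.05, n_trials=15, photostim=False,
        )
        assert res["rejected"].shape == (3,)
        assert 0.0 <= res["rejection_fraction"] <= 1.0
        assert np.isfinite(res["loss_curves"]).all()


class TestConnectivityAnalysis:
    def test_untrained_null_nonsignificant(self):
        """Before-vs-before differences carry no signal."""
        rng = np.random.default_rng(13)
        pairs_delta = []
        cfg = RNNConfig(n=40, d=5)
        for s in range(3):
            model = rnn.init_model(cfg, s)
            W1 = rnn.insilico_photostim(model, rng=np.random.default_rng(s))
            W2 = rnn.insilico_photostim(model, rng=np.random.default_rng(s + 50))
            stab1 = rnn.run_stabilization(model, np.random.default_rng(s + 100), 4)
            stab2 = rnn.run_stabilization(model, np.random.default_rng(s + 200), 4)
            C1 = rnn.stabilization_correlations(stab1)
            C2 = rnn.stabilization_correlations(stab2)
            pairs_delta.append((C2 - C1, W2 - W1))
        out = rnn.model_connectivity_analysis(pairs_delta, pairs_delta)
        assert out["dcorr_vs_dW"]["p"] > 0.001
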