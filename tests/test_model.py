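"""Network forward ops, analytic gradients, training behaviour."""

import numpy as np
import pytest

from hazchemnet import (
    HazChemNet,
    TrainingConfig,
    attention_weights,
    decode,
    encode,
    encode_weighted,
    expert_outputs,
    gate,
    moe_predict,
    reconstruction_loss,
    train_autoencoder,
    train_moe,
)
from hazchemnet.model import (
    AutoencoderParams,
    MoEParams,
    _ae_loss_and_grads,
    _moe_loss_and_grads,
    stable_softmax,
)


def tiny_ae(n_in=7, hidden=5, latent=4, seed=0):
    return AutoencoderParams.init(n_in, hidden, latent,
                                  np.random.default_rng(seed))


def tiny_moe(latent=4, expert_hidden=3, n_experts=3, seed=0):
    return MoEParams.init(latent, expert_hidden, n_experts,
                          np.random.default_rng(seed))


class TestEncode:
    def test_zero_weights_give_zero_latent(self):
        p = tiny_ae()
        for name in ("W1", "b1", "W2", "b2"):
            getattr(p, name)[...] = 0.0
        np.testing.assert_array_equal(encode(np.ones(7), p), np.zeros(4))

    def test_identity_1d_positive(self):
        p = AutoencoderParams(
            W1=np.array([[1.0]]), b1=np.zeros(1), W2=np.array([[1.0]]),
            b2=np.zeros(1), Wa=np.zeros((1, 1)), ba=np.zeros(1),
            W3=np.array([[1.0]]), b3=np.zeros(1), W4=np.array([[1.0]]),
            b4=np.zeros(1))
        assert encode(np.array([3.0]), p)[0] == 3.0
        assert encode(np.array([-5.0]), p)[0] == 0.0  # ReLU clamps

    def test_nonnegative_output(self, rng):
        p = tiny_ae()
        Z = encode(rng.normal(size=(20, 7)), p)
        assert np.all(Z >= 0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            encode(np.ones(9), tiny_ae())


class TestAttention:
    def test_uniform_when_scores_equal(self):
        z = np.array([4.0, 2.0])
        alpha, zp = attention_weights(z, np.zeros((2, 2)), np.zeros(2))
        np.testing.assert_allclose(alpha, [0.5, 0.5])
        np.testing.assert_allclose(zp, [2.0, 1.0])

    def test_sums_to_one_and_positive(self, rng):
        p = tiny_ae(latent=6)
        for _ in range(25):
            z = rng.normal(scale=10.0, size=6)
            alpha, _ = attention_weights(z, p.Wa, p.ba)
            assert abs(alpha.sum() - 1.0) < 1e-12
            assert np.all(alpha > 0)

    def test_softmax_overflow_free(self):
        u = np.array([1e4, -1e4, 0.0])
        s = stable_softmax(u)
        assert np.isfinite(s).all() and abs(s.sum() - 1.0) < 1e-12


class TestDecodeAndLoss:
    def test_zero_weights_zero_reconstruction(self):
        p = tiny_ae()
        for name in ("W3", "b3", "W4", "b4"):
            getattr(p, name)[...] = 0.0
        np.testing.assert_array_equal(decode(np.ones(4), p), np.zeros(7))

    def test_identity_toy_round_trip(self):
        # 1-D network of identity weights; softmax over one latent dim is 1
        p = AutoencoderParams(
            W1=np.eye(1), b1=np.zeros(1), W2=np.eye(1), b2=np.zeros(1),
            Wa=np.zeros((1, 1)), ba=np.zeros(1), W3=np.eye(1),
            b3=np.zeros(1), W4=np.eye(1), b4=np.zeros(1))
        x = np.array([3.0])
        assert decode(encode_weighted(x, p), p)[0] == pytest.approx(3.0)

    def test_mse_matches_loop_oracle(self, rng):
        X = rng.normal(size=(8, 5))
        Xh = rng.normal(size=(8, 5))
        acc = 0.0
        for i in range(8):
            for j in range(5):
                acc += (X[i, j] - Xh[i, j]) ** 2
        assert reconstruction_loss(X, Xh) == pytest.approx(acc / 40,
                                                           abs=1e-12)

    def test_mse_zero_iff_equal(self, rng):
        X = rng.normal(size=(4, 3))
        assert reconstruction_loss(X, X) == 0.0
        assert reconstruction_loss(np.array([[1.0, 0.0]]),
                                   np.array([[0.0, 0.0]])) == 0.5


class TestMixtureOfExperts:
    def test_single_expert_gate_is_one(self, rng):
        m = tiny_moe(n_experts=1)
        g = gate(rng.normal(size=4), m)
        np.testing.assert_allclose(g, [1.0])

    def test_uniform_gate_when_scores_equal(self):
        m = tiny_moe(n_experts=4)
        m.Wg[...] = 0.0
        m.bg[...] = 0.0
        np.testing.assert_allclose(gate(np.ones(4), m), 0.25)

    def test_gate_sums_to_one(self, rng):
        m = tiny_moe()
        G = gate(rng.normal(scale=5.0, size=(30, 4)), m)
        np.testing.assert_allclose(G.sum(axis=1), 1.0, atol=1e-12)

    def test_mixture_is_convex_combination(self, rng):
        m = tiny_moe(n_experts=5)
        Zp = rng.normal(size=(40, 4))
        y = moe_predict(Zp, m)
        Y = expert_outputs(Zp, m)
        assert np.all(y >= Y.min(axis=1) - 1e-12)
        assert np.all(y <= Y.max(axis=1) + 1e-12)
        assert np.all((y >= 0) & (y <= 1))

    def test_equal_experts_ignore_gating(self):
        m = tiny_moe(n_experts=3)
        # force every expert to output sigmoid(logit) = 0.7
        m.U[...] = 0.0
        m.c[...] = 0.0
        m.v[...] = 0.0
        m.d[...] = np.log(0.7 / 0.3)
        y = moe_predict(np.array([1.0, -2.0, 0.5, 3.0]), m)
        assert y == pytest.approx(0.7, abs=1e-12)

    def test_hand_mixture(self):
        # y = 0·0.25 + 1·0.75 computed through the convex-combination rule
        g = np.array([0.25, 0.75])
        ym = np.array([0.0, 1.0])
        assert float(np.sum(g * ym)) == 0.75


class TestGradients:
    """Analytic gradients agree with central finite differences."""

    def test_autoencoder_gradients(self, rng):
        p = tiny_ae()
        X = rng.normal(size=(6, 7))
        _, grads = _ae_loss_and_grads(p, X)
        eps = 1e-6
        for name, arr in p.to_dict().items():
            for _ in range(min(arr.size, 8)):
                idx = tuple(rng.integers(0, s) for s in arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _ = _ae_loss_and_grads(p, X)
                arr[idx] = orig - eps
                lm, _ = _ae_loss_and_grads(p, X)
                arr[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(num, abs=1e-7), name

    def test_moe_gradients_and_input_gradient(self, rng):
        m = tiny_moe()
        Zp = rng.normal(size=(6, 4))
        t = rng.integers(0, 2, size=6)
        _, grads, dZp = _moe_loss_and_grads(m, Zp, t, want_dzp=True)
        eps = 1e-6
        for name, arr in m.to_dict().items():
            for _ in range(min(arr.size, 8)):
                idx = tuple(rng.integers(0, s) for s in arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _, _ = _moe_loss_and_grads(m, Zp, t)
                arr[idx] = orig - eps
                lm, _, _ = _moe_loss_and_grads(m, Zp, t)
                arr[idx] = orig
                assert grads[name][idx] == pytest.approx(
                    (lp - lm) / (2 * eps), abs=1e-7), name
        for _ in range(10):
            i = int(rng.integers(0, 6))
            j = int(rng.integers(0, 4))
            orig = Zp[i, j]
            Zp[i, j] = orig + eps
            lp, _, _ = _moe_loss_and_grads(m, Zp, t)
            Zp[i, j] = orig - eps
            lm, _, _ = _moe_loss_and_grads(m, Zp, t)
            Zp[i, j] = orig
            assert dZp[i, j] == pytest.approx((lp - lm) / (2 * eps), abs=1e-7)


class TestTraining:
    def test_autoencoder_loss_decreases(self, small_separable_data, fast_cfg):
        from hazchemnet import apply_standardizer, fit_standardizer

        X = small_separable_data.X
        std = fit_standardizer(X)
        Xs = apply_standardizer(X, std)
        _, trace = train_autoencoder(Xs[:150], Xs[150:], fast_cfg)
        assert trace.train[-1] < trace.train[0]  # descent on the fit set
        assert len(trace.train) == len(trace.val) == fast_cfg.ae_epochs
        assert all(v >= 0 for v in trace.train)

    def test_autoencoder_seed_determinism(self, small_separable_data, fast_cfg):
        from hazchemnet import apply_standardizer, fit_standardizer

        X = small_separable_data.X
        Xs = apply_standardizer(X, fit_standardizer(X))
        _, t1 = train_autoencoder(Xs[:100], Xs[100:], fast_cfg)
        _, t2 = train_autoencoder(Xs[:100], Xs[100:], fast_cfg)
        assert t1.train[-1] == pytest.approx(t2.train[-1], abs=1e-6)

    def test_autoencoder_beats_variance_baseline(self, fast_cfg):
        # data with 5 latent factors should compress well below total variance
        rng = np.random.default_rng(5)
        F = rng.normal(size=(300, 5))
        W = rng.normal(size=(5, 40))
        X = F @ W + 0.1 * rng.normal(size=(300, 40))
        from hazchemnet import apply_standardizer, fit_standardizer
        import dataclasses

        Xs = apply_standardizer(X, fit_standardizer(X))
        cfg = dataclasses.replace(fast_cfg, ae_epochs=60, latent_dim=8)
        _, trace = train_autoencoder(Xs[:250], Xs[250:], cfg)
        assert trace.val[-1] < 0.5  # total variance of standardized data is 1

    def test_moe_separable_latents(self, fast_cfg, rng):
        import dataclasses

        n = 200
        y = np.repeat([0, 1], n // 2)
        Zp = rng.normal(size=(n, 6)) + 4.0 * y[:, None]
        cfg = dataclasses.replace(fast_cfg, moe_epochs=150)
        m, trace = train_moe(Zp, y, Zp, y, cfg)
        acc = ((moe_predict(Zp, m) >= 0.5) == y).mean()
        assert acc >= 0.98
        assert trace.train[-1] < trace.train[0]

    def test_moe_single_class_rejected(self, fast_cfg, rng):
        Zp = rng.normal(size=(20, 4))
        with pytest.raises(ValueError):
            train_moe(Zp, np.ones(20), Zp, np.ones(20), fast_cfg)

    def test_moe_seed_determinism(self, fast_cfg, rng):
        y = np.repeat([0, 1], 30)
        Zp = rng.normal(size=(60, 4)) + y[:, None]
        m1, _ = train_moe(Zp, y, Zp, y, fast_cfg)
        m2, _ = train_moe(Zp, y, Zp, y, fast_cfg)
        for k, v in m1.to_dict().items():
            np.testing.assert_array_equal(v, m2.to_dict()[k])


class TestBundle:
    def test_fit_predict_on_own_training_set(self, small_separable_data):
        """Separable toy data is classified near-perfectly after end-to-end
        training (fine-tuning lets the supervised loss reach the encoder)."""
        cfg = TrainingConfig(ae_epochs=30, moe_epochs=80, hidden_dim=64,
                             latent_dim=16, expert_hidden=16, n_experts=2,
                             seed=4, joint_finetune=True, finetune_epochs=100)
        d = small_separable_data
        model = HazChemNet.fit(d.X, d.y, cfg=cfg)
        assert (model.predict(d.X) == d.y).mean() >= 0.98

    def test_threshold_tie_classifies_hazardous(self, small_separable_data,
                                                fast_cfg):
        d = small_separable_data
        model = HazChemNet.fit(d.X, d.y, cfg=fast_cfg)
        assert (np.array([0.5]) >= model.config.decision_threshold).all()
        # classification rule: probability ≥ threshold → hazardous
        proba = model.predict_proba(d.X[:5])
        np.testing.assert_array_equal(
            model.predict(d.X[:5]),
            (proba >= model.config.decision_threshold).astype(int))

    def test_empty_input_empty_output(self, small_separable_data, fast_cfg):
        d = small_separable_data
        model = HazChemNet.fit(d.X, d.y, cfg=fast_cfg)
        assert model.predict_proba(np.empty((0, 516))).size == 0

    def test_save_load_round_trip(self, tmp_path, small_separable_data,
                                  fast_cfg):
        d = small_separable_data
        model = HazChemNet.fit(d.X, d.y, cfg=fast_cfg)
        model.save(tmp_path / "bundle")
        loaded = HazChemNet.load(tmp_path / "bundle")
        np.testing.assert_allclose(loaded.predict_proba(d.X[:20]),
                                   model.predict_proba(d.X[:20]), atol=1e-12)
        assert loaded.config == model.config

    def test_attention_focuses_informative_latents(self):
        """After end-to-end training on data whose class signal lives in a
        known latent subspace, attention mass on informative latent
        dimensions exceeds mass on noise dimensions (recovery proxy)."""
        import dataclasses
        from hazchemnet import (SyntheticSpec, apply_standardizer,
                                fit_standardizer, generate_synthetic_features)
        from hazchemnet.model import attention_weights, encode

        syn = generate_synthetic_features(
            SyntheticSpec(n_per_class=150, seed=9, n_informative=10))
        cfg = TrainingConfig(ae_epochs=40, moe_epochs=60, hidden_dim=64,
                             latent_dim=12, expert_hidden=8, n_experts=2,
                             seed=9, joint_finetune=True, finetune_epochs=30)
        model = HazChemNet.fit(syn.X, syn.y, cfg=cfg)
        Xs = apply_standardizer(syn.X, model.standardizer)
        Z = encode(Xs, model.autoencoder)
        alpha, _ = attention_weights(Z, model.autoencoder.Wa,
                                     model.autoencoder.ba)
        # informative latent dims = those whose code differs across classes
        mean_diff = np.abs(Z[syn.y == 1].mean(0) - Z[syn.y == 0].mean(0))
        informative = np.argsort(mean_diff)[-4:]
        noise = np.argsort(mean_diff)[:4]
        assert alpha.mean(0)[informative].mean() > alpha.mean(0)[noise].mean()
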