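"""Architecture contracts, gradient correctness, and training behavior."""

import numpy as np
import pytest

from attnms1 import nn
from attnms1.alphabet import Alphabet
from attnms1.attention_model import AttentionIntensityModel, ModelConfig
from attnms1.encoding import encode_batch
from attnms1.synthetic import generate, preset


def random_onehot_batch(rng, n, T, A):
    X = np.zeros((n, T, A), dtype=np.float32)
    idx = rng.integers(0, A, size=(n, T))
    X[np.arange(n)[:, None], np.arange(T), idx] = 1.0
    return X


@pytest.fixture
def tiny_model():
    cfg = ModelConfig(units=4, max_len=6, alphabet_size=5, seed=7)
    return AttentionIntensityModel(cfg, Alphabet(residues="ABCD"))


class TestShapesAndDeterminism:
    def test_encoder_state_shapes(self, rng):
        cfg = ModelConfig(units=16, max_len=40, alphabet_size=21, seed=0)
        model = AttentionIntensityModel(cfg)
        X = random_onehot_batch(rng, 2, 40, 21)
        H, s = model.encode(X)
        assert H.shape == (2, 40, 32)
        assert s.shape == (2, 32)
        assert np.all(np.isfinite(H))

    def test_encoder_deterministic(self, rng, tiny_model):
        X = random_onehot_batch(rng, 3, 6, 5)
        H1, _ = tiny_model.encode(X)
        H2, _ = tiny_model.encode(X)
        assert np.array_equal(H1, H2)

    def test_wrong_channel_count_is_error(self, rng, tiny_model):
        X = random_onehot_batch(rng, 2, 6, 4)
        with pytest.raises(ValueError, match="shape"):
            tiny_model.encode(X)

    def test_predictions_batched_and_deterministic(self, rng, tiny_model):
        X = random_onehot_batch(rng, 3, 6, 5)
        results = tiny_model.predict(X)
        assert len(results) == 3
        again = tiny_model.predict(X)
        assert all(r1.y_hat == r2.y_hat for r1, r2 in zip(results, again))

    def test_same_seed_same_initial_weights(self):
        cfg = ModelConfig(units=4, max_len=6, alphabet_size=5, seed=3)
        a = AttentionIntensityModel(cfg, Alphabet(residues="ABCD"))
        b = AttentionIntensityModel(cfg, Alphabet(residues="ABCD"))
        for k, v in nn.flatten_params(a.params).items():
            assert np.array_equal(v, nn.flatten_params(b.params)[k])


class TestAttentionMechanism:
    def test_weights_nonnegative_and_sum_to_one(self, rng, tiny_model):
        X = random_onehot_batch(rng, 8, 6, 5)
        _, alphas = tiny_model.predict_with_attention(X)
        assert np.all(alphas >= 0)
        assert np.max(np.abs(alphas.sum(axis=1) - 1.0)) < 1e-6

    def test_equal_scores_give_uniform_weights(self, rng):
        # zeroed attention parameters force all scores equal
        p = nn.attention_params(np.random.default_rng(0), 4, 3)
        for k in p:
            p[k][...] = 0.0
        H = rng.standard_normal((2, 5, 4)).astype(np.float32)
        s = rng.standard_normal((2, 4)).astype(np.float32)
        _, alpha, _, _ = nn.attention_forward(s, H, p)
        assert np.allclose(alpha, 0.2, atol=1e-7)

    def test_dominant_score_selects_that_state(self, rng):
        p = nn.attention_params(np.random.default_rng(1), 2, 2)
        H = rng.standard_normal((1, 4, 2)).astype(np.float64)
        s = rng.standard_normal((1, 2)).astype(np.float64)
        _, alpha, e, cache = nn.attention_forward(s, H, p)
        # emulate a dominant first score by masking all but position 0
        mask = np.array([[False, True, True, True]])
        context, alpha, _, _ = nn.attention_forward(s, H, p, pad_mask=mask)
        assert alpha[0, 0] == pytest.approx(1.0)
        assert np.allclose(context[0], H[0, 0])

    def test_context_equals_brute_force_weighted_sum(self, rng):
        # random small instances (T <= 5, units <= 4) against direct summation
        for trial in range(10):
            T = int(rng.integers(2, 6))
            D = int(rng.integers(2, 9))
            p = nn.attention_params(np.random.default_rng(trial), D, 4,
                                    dtype=np.float64)
            H = rng.standard_normal((3, T, D))
            s = rng.standard_normal((3, D))
            context, alpha, _, _ = nn.attention_forward(s, H, p)
            brute = np.stack([
                sum(alpha[b, t] * H[b, t] for t in range(T)) for b in range(3)
            ])
            assert np.allclose(context, brute, atol=1e-6)

    def test_channel_permutation_invariance(self, rng):
        # permuting alphabet channels together with the input representation
        # leaves predictions unchanged
        cfg = ModelConfig(units=8, max_len=6, alphabet_size=5, seed=11)
        model = AttentionIntensityModel(cfg, Alphabet(residues="ABCD"))
        X = random_onehot_batch(rng, 4, 6, 5)
        perm = rng.permutation(5)
        Xp = X[:, :, perm]
        permuted = AttentionIntensityModel(cfg, Alphabet(residues="ABCD"))
        for enc in ("enc_f", "enc_b"):
            permuted.params[enc]["Wx"] = model.params[enc]["Wx"][perm]
        y1, a1 = model.predict_with_attention(X)
        y2, a2 = permuted.predict_with_attention(Xp)
        assert np.allclose(y1, y2, atol=1e-5)
        assert np.allclose(a1, a2, atol=1e-5)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        cfg = ModelConfig(units=3, max_len=5, alphabet_size=5, seed=3)
        model = AttentionIntensityModel(cfg, Alphabet(residues="ABCD"),
                                        dtype=np.float64)
        rng = np.random.default_rng(0)
        X = random_onehot_batch(rng, 4, 5, 5).astype(np.float64)
        y = rng.normal(size=4)

        def loss():
            y_hat, _, _ = model._forward(X)
            return np.mean((y_hat - y) ** 2)

        y_hat, _, cache = model._forward(X)
        grads = nn.flatten_params(model._backward(2.0 / 4 * (y_hat - y), cache))
        flat = nn.flatten_params(model.params)
        eps = 1e-6
        checked = 0
        for key, p in flat.items():
            g = grads[key]
            for _ in range(min(4, p.size)):
                i = tuple(rng.integers(0, s) for s in p.shape) if p.ndim else ()
                orig = p[i]
                p[i] = orig + eps
                lp = loss()
                p[i] = orig - eps
                lm = loss()
                p[i] = orig
                fd = (lp - lm) / (2 * eps)
                assert g[i] == pytest.approx(fd, rel=1e-3, abs=1e-7), key
                checked += 1
        assert checked > 40  # every parameter tensor sampled


class TestTraining:
    def test_loss_decreases_on_learnable_data(self):
        ds = generate(preset("POC1", n_sequences=400, seed=5))
        X = encode_batch(ds.sequences, ds.spec.alphabet, ds.spec.max_len)
        y = (ds.targets - ds.targets.min()) / np.ptp(ds.targets)
        cfg = ModelConfig(units=8, max_len=8, alphabet_size=10,
                          batch_size=32, epochs=5, seed=5)
        model = AttentionIntensityModel(cfg, ds.spec.alphabet)
        history = model.fit(X, y)
        assert history["loss"][-1] < history["loss"][0]

    def test_constant_targets_converge_to_constant(self, rng):
        X = random_onehot_batch(rng, 200, 6, 5)
        y = np.full(200, 0.37)
        cfg = ModelConfig(units=4, max_len=6, alphabet_size=5,
                          batch_size=32, epochs=25, seed=1)
        model = AttentionIntensityModel(cfg, Alphabet(residues="ABCD"))
        history = model.fit(X, y)
        assert history["loss"][-1] < 1e-3
        pred = model.predict_values(X)
        assert np.mean(np.abs(pred - 0.37)) < 0.03
        assert np.max(np.abs(pred - 0.37)) < 0.1

    def test_empty_dataset_is_error(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.fit(np.zeros((0, 6, 5)), np.zeros(0))

    def test_validation_history_recorded(self, rng):
        X = random_onehot_batch(rng, 64, 6, 5)
        y = rng.normal(size=64)
        cfg = ModelConfig(units=4, max_len=6, alphabet_size=5,
                          batch_size=16, epochs=3, seed=1)
        model = AttentionIntensityModel(cfg, Alphabet(residues="ABCD"))
        history = model.fit(X[:48], y[:48], X[48:], y[48:])
        assert len(history["val_mae"]) == 3


def test_save_load_round_trip(tmp_path, rng, tiny_model):
    X = random_onehot_batch(rng, 3, 6, 5)
    tiny_model.save(tmp_path / "model")
    loaded = AttentionIntensityModel.load(tmp_path / "model")
    assert loaded.alphabet == tiny_model.alphabet
    assert np.array_equal(loaded.predict_values(X),
                          tiny_model.predict_values(X))
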