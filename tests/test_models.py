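"""Regression models: MLR/PLSR oracles, Transformer geometry and training."""

import numpy as np
import pytest

from salmonhsi.models import (
    MLPRegressor,
    TrainingProtocol,
    TransformerConfig,
    attention_importance,
    mlp_fit,
    mlr_fit,
    mlr_predict,
    patches_to_tokens,
    plsr_fit,
    train,
    transformer_build,
)
from salmonhsi.evaluation import r2_score


# ---------------------------------------------------------------- MLR

class TestMLR:
    def test_exact_linear_fit(self, rng):
        X = rng.random((20, 3))
        y = X @ [1.0, -2.0, 0.5] + 3.0
        model = mlr_fit(X, y)
        assert np.allclose(mlr_predict(model, X), y, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.random((20, 3))
        y = rng.random(20)
        model = mlr_fit(X, y)
        A = np.column_stack([np.ones(20), X])
        expected = np.linalg.solve(A.T @ A, A.T @ y)
        assert np.allclose(model.coef, expected, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        X = rng.random((30, 4))
        y = rng.random(30)
        model = mlr_fit(X, y)
        resid = y - mlr_predict(model, X)
        assert np.allclose(X.T @ resid, 0.0, atol=1e-9)

    def test_duplicated_column_is_error(self, rng):
        X = rng.random((20, 3))
        X[:, 2] = X[:, 0]
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            mlr_fit(X, rng.random(20))

    def test_underdetermined_rejected(self, rng):
        with pytest.raises(ValueError, match="N > p"):
            mlr_fit(rng.random((5, 8)), rng.random(5))


# ---------------------------------------------------------------- PLSR

def _nipals_oracle(X, y, n_components):
    """Textbook NIPALS with deflation, centered data, single response."""
    X = X - X.mean(axis=0)
    y = y - y.mean()
    W, P, Q, T = [], [], [], []
    Xk, yk = X.copy(), y.copy()
    for _ in range(n_components):
        w = Xk.T @ yk
        w /= np.linalg.norm(w)
        t = Xk @ w
        p = Xk.T @ t / (t @ t)
        q = yk @ t / (t @ t)
        Xk = Xk - np.outer(t, p)
        yk = yk - q * t
        W.append(w); P.append(p); Q.append(q); T.append(t)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    beta = W @ np.linalg.solve(P.T @ W, Q)
    return beta


class TestPLSR:
    def test_matches_independent_nipals_oracle(self, rng):
        X = rng.random((30, 10))
        y = X @ rng.normal(size=10) + rng.normal(0, 0.2, 30)
        model = plsr_fit(X, y, max_components=4)
        k = model.n_components
        beta = _nipals_oracle(X, y, k)
        expected = (X - X.mean(axis=0)) @ beta + y.mean()
        assert np.allclose(model.predict(X), expected, atol=1e-8)

    def test_full_rank_equals_ols(self, rng):
        X = rng.random((25, 4))
        y = rng.random(25)
        beta = _nipals_oracle(X, y, 4)
        pls_pred = (X - X.mean(axis=0)) @ beta + y.mean()
        ols = mlr_fit(X, y)
        assert np.allclose(pls_pred, mlr_predict(ols, X), atol=1e-8)

    def test_first_weight_proportional_to_xty(self, rng):
        X = rng.random((30, 6))
        y = rng.random(30)
        Xc, yc = X - X.mean(axis=0), y - y.mean()
        model = plsr_fit(X, y, max_components=3)
        w1 = model.x_weights_[:, 0]
        expected = Xc.T @ yc
        expected /= np.linalg.norm(expected)
        assert np.allclose(np.abs(w1), np.abs(expected), atol=1e-8)

    def test_zero_variance_response_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            plsr_fit(rng.random((20, 5)), np.full(20, 3.0))


# ---------------------------------------------------------------- geometry

class TestTransformerGeometry:
    def test_patch_flattens_to_4096_tokens(self, rng):
        patches = rng.random((2, 64, 64, 7)).astype(np.float32)
        tokens = patches_to_tokens(patches)
        assert tokens.shape == (2, 4096, 7)

    def test_desk_scale_pooling(self, rng):
        patches = rng.random((3, 64, 64, 5)).astype(np.float32)
        tokens = patches_to_tokens(patches, (16, 16))
        assert tokens.shape == (3, 256, 5)
        # pooled token 0 is the mean of the top-left 4x4 block
        assert np.allclose(tokens[0, 0], patches[0, :4, :4].mean(axis=(0, 1)),
                           atol=1e-6)

    def test_full_scale_embedding_shape(self, rng):
        """Input batch 2 x 4096 x 158 embeds into a 256-dim hidden space."""
        model = transformer_build(TransformerConfig(), seed=0)
        x = rng.random((2, 4096, 158)).astype(np.float32)
        embedded = model.input_proj.forward(x, train=False)
        assert embedded.shape == (2, 4096, 256)

    def test_output_nonnegative_scalar(self, rng):
        cfg = TransformerConfig(n_tokens=16, n_bands_in=6, d_model=16,
                                n_layers=1, n_heads=4, dropout=0.0)
        model = transformer_build(cfg, seed=0)
        model.scaler.mu = -5.0        # force raw de-standardised values < 0
        out = model.predict(rng.standard_normal((4, 16, 6)).astype(np.float32))
        assert out.shape == (4,)
        assert np.all(out >= 0.0)

    def test_heads_must_divide_width(self):
        with pytest.raises(ValueError, match="divisible"):
            TransformerConfig(d_model=30, n_heads=8)

    def test_pooling_permutation_invariance_without_encoding(self, rng):
        cfg = TransformerConfig(n_tokens=12, n_bands_in=5, d_model=16,
                                n_layers=2, n_heads=4, dropout=0.0,
                                positional_encoding="none")
        model = transformer_build(cfg, seed=0)
        x = rng.standard_normal((3, 12, 5)).astype(np.float32)
        perm = rng.permutation(12)
        a = model.forward_standardised(x)
        b = model.forward_standardised(x[:, perm, :])
        assert np.allclose(a, b, atol=1e-5)

    def test_positional_encoding_breaks_permutation_invariance(self, rng):
        cfg = TransformerConfig(n_tokens=12, n_bands_in=5, d_model=16,
                                n_layers=2, n_heads=4, dropout=0.0)
        model = transformer_build(cfg, seed=0)
        x = rng.standard_normal((3, 12, 5)).astype(np.float32)
        perm = np.roll(np.arange(12), 5)
        assert not np.allclose(model.forward_standardised(x),
                               model.forward_standardised(x[:, perm, :]),
                               atol=1e-5)


# ---------------------------------------------------------------- gradients

def test_backpropagation_matches_finite_differences(rng):
    """Analytic gradients of the full graph agree with central differences."""
    cfg = TransformerConfig(n_tokens=6, n_bands_in=5, d_model=8, n_layers=2,
                            n_heads=2, head_dims=(4, 1), dropout=0.0, ff_mult=2)
    model = transformer_build(cfg, seed=0)
    for p in model.params():                      # float64 for exact numerics
        p.value = p.value.astype(np.float64)
        p.grad = np.zeros_like(p.value)
    x = rng.standard_normal((3, 6, 5))
    y = rng.standard_normal(3)

    pred = model._forward_net(x, True)
    model._backward_net((2.0 / 3) * (pred - y))

    def loss():
        return float(np.mean((model._forward_net(x, False) - y) ** 2))

    eps = 1e-6
    for p in model.params():
        flat = p.value.ravel()
        j = flat.size // 2
        orig = flat[j]
        flat[j] = orig + eps
        lp = loss()
        flat[j] = orig - eps
        lm = loss()
        flat[j] = orig
        numeric = (lp - lm) / (2 * eps)
        analytic = p.grad.ravel()[j]
        assert analytic == pytest.approx(numeric, abs=2e-6)


# ---------------------------------------------------------------- training

class TestTrainingProtocol:
    def _toy_model(self, seed=0):
        cfg = TransformerConfig(n_tokens=8, n_bands_in=6, d_model=8,
                                n_layers=1, n_heads=2, head_dims=(8, 1),
                                dropout=0.0, ff_mult=2)
        return transformer_build(cfg, seed=seed)

    def _toy_data(self, rng, n=24):
        X = rng.standard_normal((n, 8, 6)).astype(np.float32)
        w = rng.standard_normal(6)
        y = 10.0 + 2.0 * (X.mean(axis=1) @ w)
        return X, np.maximum(y, 0.1)

    def test_overfits_small_batch(self, rng):
        """Capacity sanity: 16 patches, permissive epochs, training R2 > 0.99."""
        X, y = self._toy_data(rng, 16)
        model = self._toy_model()
        proto = TrainingProtocol(lr=5e-3, max_epochs=500,
                                 early_stop_patience=500,
                                 scheduler_patience=400, batch_size=16, seed=0)
        train(model, (X, y), (X, y), proto)
        assert r2_score(y, model.predict(X)) > 0.99

    class _FrozenModel:
        """Constant predictor: validation loss can never improve, which
        exposes the plateau scheduler and early-stopping logic exactly."""

        def __init__(self):
            from salmonhsi import nn
            from salmonhsi.models import _LabelScaler
            self._p = nn.Param(np.zeros(1))
            self.scaler = _LabelScaler()
            self.history = []
            self.provenance = {}

        def params(self):
            return [self._p]

        def state(self):
            return [self._p.value.copy()]

        def load_state(self, state):
            self._p.value[...] = state[0]

        def forward_standardised(self, X, train=False):
            return np.zeros(len(X), dtype=np.float32)

        def _backward_net(self, grad):
            pass

    def test_early_stopping_on_flat_validation(self, rng):
        X = rng.random((16, 4)).astype(np.float32)
        y = rng.random(16)
        model = self._FrozenModel()
        proto = TrainingProtocol(lr=1e-3, max_epochs=200,
                                 early_stop_patience=30, batch_size=8, seed=0)
        train(model, (X, y), (X, y), proto)
        assert len(model.history) == 31          # stopped long before 200

    def test_scheduler_halves_lr_with_floor(self, rng):
        X = rng.random((16, 4)).astype(np.float32)
        y = rng.random(16)
        model = self._FrozenModel()
        proto = TrainingProtocol(lr=1e-4, max_epochs=200,
                                 scheduler_patience=15, early_stop_patience=999,
                                 lr_floor=5e-7, batch_size=8, seed=0)
        train(model, (X, y), (X, y), proto)
        lrs = [h["lr"] for h in model.history]
        assert lrs[0] == pytest.approx(1e-4)
        assert min(lrs) >= 5e-7                  # floor respected
        assert pytest.approx(5e-5) in lrs        # halving applied after plateau
        assert lrs[-1] == pytest.approx(5e-7)    # eventually pinned at floor

    def test_best_so_far_validation_monotone(self, rng):
        X, y = self._toy_data(rng)
        model = self._toy_model()
        proto = TrainingProtocol(lr=1e-3, max_epochs=30, batch_size=8, seed=0)
        train(model, (X[:18], y[:18]), (X[18:], y[18:]), proto)
        best = np.minimum.accumulate([h["val_loss"] for h in model.history])
        assert np.all(np.diff(best) <= 1e-12)

    def test_protocol_validation(self):
        with pytest.raises(ValueError, match="floor"):
            TrainingProtocol(lr=1e-7, lr_floor=5e-7)


class TestMLP:
    def test_deterministic_under_seed(self, rng):
        X = rng.random((30, 10))
        y = X @ rng.normal(size=10) + 5
        proto = TrainingProtocol(lr=1e-3, max_epochs=10, batch_size=8, seed=4)
        a = mlp_fit(X, y, hidden_sizes=(16, 8), protocol=proto)
        b = mlp_fit(X, y, hidden_sizes=(16, 8), protocol=proto)
        assert np.allclose(a.predict(X), b.predict(X))

    def test_beats_constant_mean_predictor(self, rng):
        X = rng.random((80, 12))
        y = 5.0 + 10.0 * X[:, 0] + rng.normal(0, 0.1, 80)
        proto = TrainingProtocol(lr=3e-3, max_epochs=120, batch_size=16,
                                 seed=0, scheduler_patience=20)
        model = mlp_fit(X[:60], y[:60], hidden_sizes=(32, 16), protocol=proto,
                        val_set=(X[60:], y[60:]))
        assert r2_score(y[60:], model.predict(X[60:])) > 0.0


class TestAttentionImportance:
    def test_normalisation_contract(self, rng):
        cfg = TransformerConfig(n_tokens=9, n_bands_in=7, d_model=16,
                                n_layers=2, n_heads=4, dropout=0.0)
        model = transformer_build(cfg, seed=1)
        imp = attention_importance(
            model, rng.standard_normal((4, 9, 7)).astype(np.float32))
        assert imp.shape == (7,)
        assert np.all(imp >= 0)
        assert imp.sum() == pytest.approx(1.0)

    def test_deterministic_at_inference(self, rng):
        cfg = TransformerConfig(n_tokens=9, n_bands_in=7, d_model=16,
                                n_layers=1, n_heads=4, dropout=0.3)
        model = transformer_build(cfg, seed=1)
        x = rng.standard_normal((4, 9, 7)).astype(np.float32)
        assert np.allclose(attention_importance(model, x),
                           attention_importance(model, x))

    def test_rejects_non_transformer(self, rng):
        mlp = MLPRegressor(5, seed=0)
        with pytest.raises(TypeError):
            attention_importance(mlp, rng.random((2, 4, 5)))
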