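"""Regression models: MLR, PLSR, MLP and the patch-token Transformer.

The Transformer treats a 64x64 fillet patch as a sequence of pixel tokens
(4096 at full resolution; a 16x16 average-pooled grid of 256 tokens is the
desk-scale configuration), each token carrying the spectrum at that pixel.
An input projection (linear -> layer-norm -> GELU -> dropout) embeds tokens
into d_model dimensions, sinusoidal positional encodings retain spatial
order, three 8-head self-attention encoder layers model long-range
spectral/spatial dependencies, and after global average pooling a cascaded
head (128 -> 64 -> 32 -> 1) regresses the freshness index.  Predictions are
floored at zero (physical non-negativity of TVB-N / TVC).

Training follows a fixed protocol: AdamW (lr 1e-4, weight decay 5e-5), MSE
loss on standardised labels, ReduceLROnPlateau (factor 0.5, patience 15,
floor 5e-7), early stopping after 30 epochs without validation improvement,
at most 200 epochs, best-validation weights restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import GroupKFold

from salmonhsi import nn

__all__ = [
    "TransformerConfig",
    "TrainingProtocol",
    "MLRModel",
    "PLSRModel",
    "MLPRegressor",
    "TransformerRegressor",
    "mlr_fit",
    "mlr_predict",
    "plsr_fit",
    "mlp_fit",
    "transformer_build",
    "train",
    "attention_importance",
    "patches_to_tokens",
]


# ---------------------------------------------------------------- configs

@dataclass(frozen=True)
class TransformerConfig:
    n_tokens: int = 4096
    n_bands_in: int = 158
    d_model: int = 256
    n_layers: int = 3
    n_heads: int = 8
    head_dims: tuple[int, ...] = (128, 64, 32, 1)
    dropout: float = 0.1
    ff_mult: int = 4
    positional_encoding: str = "sinusoidal"

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.head_dims[-1] != 1:
            raise ValueError("regression head must end in a single output")
        if self.positional_encoding not in ("sinusoidal", "none"):
            raise ValueError("positional_encoding must be sinusoidal or none")


@dataclass(frozen=True)
class TrainingProtocol:
    lr: float = 1e-4
    weight_decay: float = 5e-5
    scheduler_factor: float = 0.5
    scheduler_patience: int = 15
    lr_floor: float = 5e-7
    max_epochs: int = 200
    early_stop_patience: int = 30
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_floor >= self.lr:
            raise ValueError("lr floor must lie below the initial lr")
        if self.scheduler_patience <= 0 or self.early_stop_patience <= 0:
            raise ValueError("patiences must be positive")


# ---------------------------------------------------------------- MLR

@dataclass
class MLRModel:
    kind: str
    coef: np.ndarray           # intercept first
    provenance: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.coef[0] + X @ self.coef[1:]


def mlr_fit(X: np.ndarray, y: np.ndarray, **provenance) -> MLRModel:
    """Ordinary least squares with intercept; errors on rank deficiency.

    Rank-deficient designs are a hard error (the caller should reduce the
    band set) rather than a silent minimum-norm pseudo-inverse solution.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need N > p for MLR; got N={n}, p={p}")
    A = np.column_stack([np.ones(n), X])
    q, r = np.linalg.qr(A)
    diag = np.abs(np.diag(r))
    if np.any(diag < 1e-10 * max(diag.max(), 1.0)):
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient after intercept augmentation; "
            "reduce the band set")
    coef = np.linalg.solve(r, q.T @ y)
    return MLRModel("mlr", coef, dict(provenance))


def mlr_predict(model: MLRModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


# ---------------------------------------------------------------- PLSR

@dataclass
class PLSRModel:
    kind: str
    pls: PLSRegression
    n_components: int
    cv_trace: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def x_scores_(self):
        return self.pls.x_scores_

    @property
    def x_loadings_(self):
        return self.pls.x_loadings_

    @property
    def x_weights_(self):
        return self.pls.x_weights_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.pls.predict(np.asarray(X, dtype=float)).ravel()


def plsr_fit(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 15,
    cv_groups: np.ndarray | None = None,
    n_folds: int = 5,
    **provenance,
) -> PLSRModel:
    """NIPALS partial least squares; component count by grouped-CV RMSE."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if np.std(y) < 1e-12:
        raise ValueError("zero-variance response")
    max_components = min(max_components, n - 1, p)
    if cv_groups is not None:
        g = np.asarray(cv_groups)
        folds = list(GroupKFold(n_splits=min(n_folds, np.unique(g).size)).split(X, y, g))
    else:
        from sklearn.model_selection import KFold
        folds = list(KFold(n_splits=min(n_folds, n), shuffle=True,
                           random_state=0).split(X, y))
    trace = np.empty(max_components)
    for ncomp in range(1, max_components + 1):
        sse, ntot = 0.0, 0
        for tr, te in folds:
            k = min(ncomp, len(tr) - 1)
            mdl = PLSRegression(n_components=k, scale=False).fit(X[tr], y[tr])
            sse += float(np.sum((y[te] - mdl.predict(X[te]).ravel()) ** 2))
            ntot += len(te)
        trace[ncomp - 1] = np.sqrt(sse / ntot)
    best = int(np.argmin(trace)) + 1
    pls = PLSRegression(n_components=best, scale=False).fit(X, y)
    return PLSRModel("plsr", pls, best, trace, dict(provenance))


# ---------------------------------------------------------------- deep nets

class _LabelScaler:
    """Standardises labels on train statistics; identity until fitted."""

    def __init__(self):
        self.mu, self.sd = 0.0, 1.0

    def fit(self, y: np.ndarray) -> None:
        self.mu = float(np.mean(y))
        self.sd = float(np.std(y)) or 1.0

    def transform(self, y):
        return (y - self.mu) / self.sd

    def inverse(self, z):
        return z * self.sd + self.mu


def patches_to_tokens(patches: np.ndarray, token_grid: tuple[int, int] | None = None
                      ) -> np.ndarray:
    """Flatten (N, H, W, B) patches into (N, tokens, B) spectral sequences.

    With a ``token_grid`` coarser than the patch, spatial average pooling
    reduces the 64x64 pixel grid to e.g. 16x16 tokens before flattening —
    the desk-scale geometry.  A 64x64 patch with no pooling yields the full
    4096-token sequence.
    """
    patches = np.asarray(patches)
    n, h, w, b = patches.shape
    if token_grid is None or token_grid == (h, w):
        return patches.reshape(n, h * w, b)
    th, tw = token_grid
    if h % th or w % tw:
        raise ValueError(f"token grid {token_grid} must divide patch {h}x{w}")
    pooled = patches.reshape(n, th, h // th, tw, w // tw, b).mean(axis=(2, 4))
    return pooled.reshape(n, th * tw, b)


class TransformerRegressor:
    """Patch-token Transformer for a single freshness index."""

    kind = "transformer"

    def __init__(self, config: TransformerConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.input_proj = nn.Sequential(
            nn.Linear(c.n_bands_in, c.d_model, rng),
            nn.LayerNorm(c.d_model),
            nn.GELU(),
            nn.Dropout(c.dropout, rng),
        )
        self.pos = nn.SinusoidalPositionalEncoding(c.n_tokens, c.d_model)
        self.pos.enabled = c.positional_encoding == "sinusoidal"
        self.encoders = [
            nn.EncoderLayer(c.d_model, c.n_heads, c.ff_mult * c.d_model, rng, c.dropout)
            for _ in range(c.n_layers)
        ]
        self.pool = nn.MeanPool()
        head_layers: list[nn.Module] = []
        dims = (c.d_model,) + tuple(c.head_dims)
        for i in range(len(dims) - 1):
            head_layers.append(nn.Linear(dims[i], dims[i + 1], rng))
            if i < len(dims) - 2:
                head_layers.append(nn.ReLU())
        self.head = nn.Sequential(*head_layers)
        self.scaler = _LabelScaler()
        self.provenance: dict = {}
        self.history: list[dict] = []

    # -- plumbing ---------------------------------------------------------
    def params(self) -> list[nn.Param]:
        out = self.input_proj.params()
        for e in self.encoders:
            out.extend(e.params())
        out.extend(self.head.params())
        return out

    def state(self):
        return [p.value.copy() for p in self.params()]

    def load_state(self, state):
        for p, s in zip(self.params(), state, strict=True):
            p.value[...] = s

    def _forward_net(self, x: np.ndarray, train: bool) -> np.ndarray:
        z = self.input_proj.forward(x, train)
        z = self.pos.forward(z, train)
        for e in self.encoders:
            z = e.forward(z, train)
        z = self.pool.forward(z, train)
        return self.head.forward(z, train).ravel()

    def _backward_net(self, grad_out: np.ndarray) -> None:
        g = self.head.backward(grad_out[:, None])
        g = self.pool.backward(g)
        for e in reversed(self.encoders):
            g = e.backward(g)
        g = self.pos.backward(g)
        self.input_proj.backward(g)

    # -- user surface -----------------------------------------------------
    def forward_standardised(self, tokens: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(tokens, dtype=np.float32)
        if x.ndim != 3 or x.shape[2] != self.config.n_bands_in:
            raise ValueError(
                f"expected (N, tokens, {self.config.n_bands_in}) input, got {x.shape}")
        return self._forward_net(x, train)

    def predict(self, tokens: np.ndarray) -> np.ndarray:
        """Physical-scale prediction, floored at zero (ReLU convention)."""
        z = self.forward_standardised(tokens, train=False)
        return np.maximum(self.scaler.inverse(z), 0.0)


class MLPRegressor:
    """Fully connected baseline on per-patch mean spectra."""

    kind = "mlp"

    def __init__(self, n_bands_in: int, hidden_sizes=(128, 64, 32), seed: int = 0):
        rng = np.random.default_rng(seed)
        dims = (n_bands_in,) + tuple(hidden_sizes) + (1,)
        layers: list[nn.Module] = []
        for i in range(len(dims) - 1):
            layers.append(nn.Linear(dims[i], dims[i + 1], rng))
            if i < len(dims) - 2:
                layers.append(nn.ReLU())
        self.net = nn.Sequential(*layers)
        self.n_bands_in = n_bands_in
        self.scaler = _LabelScaler()
        self.provenance: dict = {}
        self.history: list[dict] = []

    def params(self):
        return self.net.params()

    def state(self):
        return [p.value.copy() for p in self.params()]

    def load_state(self, state):
        for p, s in zip(self.params(), state, strict=True):
            p.value[...] = s

    def forward_standardised(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(np.asarray(X, dtype=np.float32), train).ravel()

    def _backward_net(self, grad_out: np.ndarray) -> None:
        self.net.backward(grad_out[:, None])

    def predict(self, X: np.ndarray) -> np.ndarray:
        z = self.forward_standardised(X, train=False)
        return np.maximum(self.scaler.inverse(z), 0.0)


def transformer_build(config: TransformerConfig, seed: int = 0) -> TransformerRegressor:
    """Build an untrained patch-token Transformer from its configuration."""
    return TransformerRegressor(config, seed)


# ---------------------------------------------------------------- training

def train(
    model,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    protocol: TrainingProtocol = TrainingProtocol(),
    verbose: bool = False,
):
    """AdamW / MSE training loop with plateau scheduling and early stopping.

    Labels are standardised with train-split statistics.  The best-validation
    weights are restored at the end and the full per-epoch history is kept on
    the model.  Deterministic under a fixed protocol seed.
    """
    Xtr, ytr = train_set
    Xva, yva = val_set
    Xtr = np.asarray(Xtr, dtype=np.float32)
    Xva = np.asarray(Xva, dtype=np.float32)
    model.scaler.fit(np.asarray(ytr, dtype=float))
    ztr = model.scaler.transform(np.asarray(ytr, dtype=float)).astype(np.float32)
    zva = model.scaler.transform(np.asarray(yva, dtype=float)).astype(np.float32)

    rng = np.random.default_rng(protocol.seed)
    opt = nn.AdamW(model.params(), lr=protocol.lr, weight_decay=protocol.weight_decay)
    best_val, best_state, best_epoch = np.inf, model.state(), -1
    plateau, stale = 0, 0
    model.history = []
    n = len(ztr)
    bs = min(protocol.batch_size, n)
    for epoch in range(protocol.max_epochs):
        order = rng.permutation(n)
        train_loss = 0.0
        for i in range(0, n, bs):
            idx = order[i:i + bs]
            opt.zero_grad()
            pred = model.forward_standardised(Xtr[idx], train=True)
            resid = pred - ztr[idx]
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            model._backward_net((2.0 / len(idx)) * resid)
            opt.step()
            train_loss += loss * len(idx)
        train_loss /= n
        val_pred = np.concatenate([
            model.forward_standardised(Xva[i:i + bs], train=False)
            for i in range(0, len(zva), bs)
        ])
        val_loss = float(np.mean((val_pred - zva) ** 2))
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        model.history.append({"epoch": epoch, "train_loss": train_loss,
                              "val_loss": val_loss, "lr": opt.lr})
        if verbose:
            print(f"epoch {epoch:3d}  train {train_loss:.5f}  "
                  f"val {val_loss:.5f}  lr {opt.lr:.2e}")
        if val_loss < best_val - 1e-12:
            best_val, best_state, best_epoch = val_loss, model.state(), epoch
            plateau, stale = 0, 0
        else:
            plateau += 1
            stale += 1
            if plateau >= protocol.scheduler_patience:
                opt.lr = max(opt.lr * protocol.scheduler_factor, protocol.lr_floor)
                plateau = 0
            if stale >= protocol.early_stop_patience:
                break
    model.load_state(best_state)
    model.provenance["best_epoch"] = best_epoch
    model.provenance["protocol"] = protocol
    return model


def mlp_fit(
    X: np.ndarray,
    y: np.ndarray,
    hidden_sizes=(128, 64, 32),
    protocol: TrainingProtocol = TrainingProtocol(),
    val_set: tuple[np.ndarray, np.ndarray] | None = None,
) -> MLPRegressor:
    """Train the MLP baseline; without a validation set, a tail split is held out."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if val_set is None:
        n_val = max(1, len(y) // 5)
        val_set = (X[-n_val:], y[-n_val:])
        X, y = X[:-n_val], y[:-n_val]
    model = MLPRegressor(X.shape[1], hidden_sizes, seed=protocol.seed)
    return train(model, (X, y), val_set, protocol)


# ---------------------------------------------------------------- attention

def attention_importance(model: TransformerRegressor, batch: np.ndarray) -> np.ndarray:
    """Per-band importance from attention maps and embedding weights.

    Attention tensors of every encoder layer are recorded on a forward pass
    of ``batch``, averaged over heads, layers and queries into per-token
    received-attention mass; the token mass is folded with the magnitude of
    the input-projection weights |W_embed| (band -> d_model), which carries
    the band axis, to yield a non-negative importance vector summing to 1.
    """
    if not isinstance(model, TransformerRegressor):
        raise TypeError("attention importance is defined for transformer models only")
    for enc in model.encoders:
        enc.attn.record_attention = True
    try:
        model.forward_standardised(batch, train=False)
    finally:
        maps = [enc.attn.last_attention for enc in model.encoders]
        for enc in model.encoders:
            enc.attn.record_attention = False
    # received attention per token: mean over batch, heads and queries, then
    # layers; total token mass is 1 by softmax normalisation
    token_mass = np.mean([a.mean(axis=(0, 1, 2)) for a in maps], axis=0)
    attention_total = float(token_mass.sum())
    # the input projection is the only layer still carrying the band axis:
    # project the aggregated attention mass through |W_embed| row magnitudes
    w_embed = model.input_proj.layers[0].W.value        # (bands, d_model)
    importance = np.abs(w_embed).sum(axis=1) * attention_total
    total = importance.sum()
    if total <= 0:
        raise ValueError("degenerate importance (all-zero embedding)")
    return importance / total
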