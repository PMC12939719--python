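"""Minimal NumPy neural-network layers with explicit reverse-mode gradients.

Everything the regression stage needs — linear, layer-norm, GELU/ReLU,
dropout, sinusoidal positional encoding, multi-head self-attention and the
AdamW optimiser — implemented directly on ndarrays with hand-derived
backward passes.  Layers cache what their backward pass needs during
``forward`` and release it when ``backward`` runs, so a module is used in
strict forward-then-backward order within a step.

Shapes follow the (batch, tokens, features) convention for sequence layers
and (batch, features) for dense stacks; ``Linear`` accepts either.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

__all__ = [
    "Param", "Module", "Linear", "LayerNorm", "GELU", "ReLU", "Dropout",
    "Sequential", "SinusoidalPositionalEncoding", "MultiHeadSelfAttention",
    "FeedForward", "EncoderLayer", "MeanPool", "AdamW",
]


class Param:
    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # excluded from weight decay when False (biases, norms)


class Module:
    def params(self) -> list[Param]:
        out: list[Param] = []
        for v in vars(self).values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train)

    # -- checkpointing ----------------------------------------------------
    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state, strict=True):
            p.value[...] = s


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / (n_in + n_out))
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out), decay=False)
        self._x: np.ndarray | None = None

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        g2 = grad.reshape(-1, grad.shape[-1])
        self.W.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        self._x = None
        return grad @ self.W.value.T


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim), decay=False)
        self.beta = Param(np.zeros(dim), decay=False)
        self.eps = eps
        self._cache = None

    def forward(self, x, train=False):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, grad):
        xhat, inv = self._cache
        self._cache = None
        self.gamma.grad += np.sum(grad * xhat, axis=tuple(range(grad.ndim - 1)))
        self.beta.grad += np.sum(grad, axis=tuple(range(grad.ndim - 1)))
        g = grad * self.gamma.value
        n = xhat.shape[-1]
        return inv * (g - g.mean(axis=-1, keepdims=True)
                      - xhat * np.mean(g * xhat, axis=-1, keepdims=True)) \
            if n > 1 else np.zeros_like(g)


_SQRT2 = math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


class GELU(Module):
    def __init__(self):
        self._x = None

    def forward(self, x, train=False):
        self._x = x
        return 0.5 * x * (1.0 + erf(x / _SQRT2))

    def backward(self, grad):
        x = self._x
        self._x = None
        cdf = 0.5 * (1.0 + erf(x / _SQRT2))
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
        return grad * (cdf + x * pdf)


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        m = self._mask
        self._mask = None
        return np.where(m, grad, 0.0)


class Dropout(Module):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / x.dtype.type(keep)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        m = self._mask
        self._mask = None
        return grad * m


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class SinusoidalPositionalEncoding(Module):
    """Additive fixed sin/cos token-position encoding (no parameters)."""

    def __init__(self, n_tokens: int, d_model: int):
        pos = np.arange(n_tokens)[:, None].astype(np.float64)
        i = np.arange(d_model // 2)[None, :]
        angle = pos / np.power(10000.0, 2 * i / d_model)
        pe = np.zeros((n_tokens, d_model), dtype=np.float32)
        pe[:, 0::2] = np.sin(angle)
        pe[:, 1::2] = np.cos(angle)[:, : d_model - d_model // 2]
        self.pe = pe
        self.enabled = True

    def forward(self, x, train=False):
        return x + self.pe[: x.shape[1]] if self.enabled else x

    def backward(self, grad):
        return grad


def _softmax_lastaxis_inplace(z: np.ndarray) -> np.ndarray:
    # subtract the max only when overflow is actually possible: attention
    # logits are usually O(10), and skipping the extra passes halves the cost
    # of the dominant (batch*heads, T, T) tensor operation
    if float(np.abs(z).max()) > 60.0:
        z -= z.max(axis=-1, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=-1, keepdims=True)
    return z


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product multi-head self-attention.

    ``record_attention=True`` stores the post-softmax attention tensor
    (batch, heads, queries, keys) of the last forward pass in
    ``last_attention`` for interpretability maps.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model, self.n_heads = d_model, n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self.record_attention = False
        self.last_attention: np.ndarray | None = None
        self._cache = None

    def _split(self, x):   # (N,T,d) -> (N*h,T,dh) contiguous
        n, t, _ = x.shape
        return np.ascontiguousarray(
            x.reshape(n, t, self.n_heads, self.d_head).transpose(0, 2, 1, 3)
        ).reshape(n * self.n_heads, t, self.d_head)

    def _merge(self, x, n):   # (N*h,T,dh) -> (N,T,d)
        t = x.shape[1]
        return np.ascontiguousarray(
            x.reshape(n, self.n_heads, t, self.d_head).transpose(0, 2, 1, 3)
        ).reshape(n, t, self.n_heads * self.d_head)

    def forward(self, x, train=False):
        n, t, _ = x.shape
        q = self._split(self.wq.forward(x, train))
        k = self._split(self.wk.forward(x, train))
        v = self._split(self.wv.forward(x, train))
        q *= 1.0 / math.sqrt(self.d_head)
        attn = np.matmul(q, k.transpose(0, 2, 1))
        attn = _softmax_lastaxis_inplace(attn)
        if self.record_attention:
            self.last_attention = attn.reshape(n, self.n_heads, t, t).copy()
        ctx = np.matmul(attn, v)
        self._cache = (q, k, v, attn, n)
        return self.wo.forward(self._merge(ctx, n), train)

    def backward(self, grad):
        q, k, v, attn, n = self._cache
        self._cache = None
        g_ctx = self._split(self.wo.backward(grad))
        g_attn = np.matmul(g_ctx, v.transpose(0, 2, 1))
        g_v = np.matmul(attn.transpose(0, 2, 1), g_ctx)
        # softmax backward over the key axis, fused into the attn buffer
        g_attn -= np.sum(g_attn * attn, axis=-1, keepdims=True)
        g_scores = np.multiply(attn, g_attn, out=attn)
        g_q = np.matmul(g_scores, k) / math.sqrt(self.d_head)
        g_k = np.matmul(g_scores.transpose(0, 2, 1), q)  # q already carries 1/sqrt(dh)
        return (self.wq.backward(self._merge(g_q, n))
                + self.wk.backward(self._merge(g_k, n))
                + self.wv.backward(self._merge(g_v, n)))


class FeedForward(Module):
    def __init__(self, d_model: int, d_hidden: int, rng, dropout: float = 0.0):
        self.net = Sequential(
            Linear(d_model, d_hidden, rng),
            GELU(),
            Dropout(dropout, rng),
            Linear(d_hidden, d_model, rng),
        )

    def forward(self, x, train=False):
        return self.net.forward(x, train)

    def backward(self, grad):
        return self.net.backward(grad)


class EncoderLayer(Module):
    """Post-norm Transformer encoder block: MHSA and FFN sublayers with
    residual connections, each followed by layer normalisation."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng,
                 dropout: float = 0.0):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.drop1 = Dropout(dropout, rng)
        self.norm1 = LayerNorm(d_model)
        self.ff = FeedForward(d_model, d_ff, rng, dropout)
        self.drop2 = Dropout(dropout, rng)
        self.norm2 = LayerNorm(d_model)

    def forward(self, x, train=False):
        x = self.norm1.forward(x + self.drop1.forward(self.attn.forward(x, train), train))
        x = self.norm2.forward(x + self.drop2.forward(self.ff.forward(x, train), train))
        return x

    def backward(self, grad):
        g = self.norm2.backward(grad)
        g = g + self.ff.backward(self.drop2.backward(g))
        g = self.norm1.backward(g)
        g = g + self.attn.backward(self.drop1.backward(g))
        return g


class MeanPool(Module):
    """Global average pooling over the token axis: (N,T,d) -> (N,d)."""

    def __init__(self):
        self._t = None

    def forward(self, x, train=False):
        self._t = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        t = self._t
        self._t = None
        return np.repeat(grad[:, None, :], t, axis=1) / t


class AdamW(Module):
    """Decoupled weight-decay Adam over a parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 weight_decay: float = 5e-5, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params_list = params
        self.lr, self.weight_decay = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params_list:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params_list, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if p.decay and self.weight_decay:
                update = update + self.weight_decay * p.value
            p.value -= self.lr * update
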