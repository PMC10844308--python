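"""Minimal numpy neural-network layers with hand-written backpropagation.

Provides exactly what the angle transformer needs: dense layers, exact GELU,
layer normalization, multi-head self-attention (bidirectional with learned
relative-position biases, or causal with none), and an AdamW optimizer with
a linear warmup/decay schedule.  All arrays are float64; shapes are
(batch, length, features) throughout.

Each layer caches its forward inputs and exposes ``backward(grad_out)``
returning the gradient with respect to its input while accumulating
parameter gradients in ``Parameter.grad``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

SQRT2 = np.sqrt(2.0)
INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: children are discovered from instance attributes."""

    def parameters(self) -> list[tuple[str, Parameter]]:
        out = []
        for name, attr in vars(self).items():
            if isinstance(attr, Parameter):
                out.append((name, attr))
            elif isinstance(attr, Module):
                out.extend((f"{name}.{k}", p) for k, p in attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        out.extend((f"{name}.{i}.{k}", p) for k, p in item.parameters())
        return out

    def zero_grad(self) -> None:
        for _, p in self.parameters():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.value.size for _, p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.value.copy() for k, p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.parameters())
        if set(params) != set(state):
            raise ValueError("state dict keys do not match module parameters")
        for k, p in params.items():
            if p.value.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.value[...] = state[k]


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        # Glorot-uniform initialization
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.W = Parameter(rng.uniform(-limit, limit, size=(d_in, d_out)))
        self.b = Parameter(np.zeros(d_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        axes = tuple(range(x.ndim - 1))
        self.W.grad += np.tensordot(x, g, axes=(axes, axes))
        self.b.grad += g.sum(axis=axes)
        return g @ self.W.value.T


class GELU(Module):
    """Exact (erf-based) GELU."""

    def __init__(self):
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return 0.5 * x * (1.0 + erf(x / SQRT2))

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        cdf = 0.5 * (1.0 + erf(x / SQRT2))
        pdf = INV_SQRT_2PI * np.exp(-0.5 * x ** 2)
        return g * (cdf + x * pdf)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        axes = tuple(range(g.ndim - 1))
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        gx = g * self.gamma.value
        mean_gx = gx.mean(axis=-1, keepdims=True)
        mean_gx_xhat = (gx * xhat).mean(axis=-1, keepdims=True)
        return inv * (gx - mean_gx - xhat * mean_gx_xhat)


def _softmax(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Module):
    """Self-attention over (B, L, D) with key masking.

    ``relative_bias_radius`` > 0 adds a learned per-head bias b[h, j - i]
    with the relative offset clipped to +-radius (the denoiser's relative
    positional signal).  ``causal=True`` restricts position i to keys <= i
    (the autoregressive baseline).
    """

    NEG = -1e9

    def __init__(self, d: int, heads: int, rng: np.random.Generator,
                 relative_bias_radius: int = 0, causal: bool = False):
        if d % heads:
            raise ValueError("embed dim must be divisible by heads")
        self.d, self.heads, self.dh = d, heads, d // heads
        self.causal = causal
        self.radius = relative_bias_radius
        self.wq = Dense(d, d, rng)
        self.wk = Dense(d, d, rng)
        self.wv = Dense(d, d, rng)
        self.wo = Dense(d, d, rng)
        if self.radius > 0:
            self.rel_bias = Parameter(np.zeros((2 * self.radius + 1, heads)))
        self._cache = None

    def _split(self, x: np.ndarray) -> np.ndarray:
        B, L, _ = x.shape
        return x.reshape(B, L, self.heads, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        B, H, L, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, L, H * dh)

    def _rel_index(self, L: int) -> np.ndarray:
        offs = np.arange(L)[None, :] - np.arange(L)[:, None]  # j - i
        return np.clip(offs, -self.radius, self.radius) + self.radius

    def forward(self, x: np.ndarray, key_mask: np.ndarray | None = None) -> np.ndarray:
        B, L, _ = x.shape
        q = self._split(self.wq.forward(x))
        k = self._split(self.wk.forward(x))
        v = self._split(self.wv.forward(x))
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.dh)  # (B,H,L,L)
        rel_idx = None
        if self.radius > 0:
            rel_idx = self._rel_index(L)
            scores = scores + self.rel_bias.value[rel_idx].transpose(2, 0, 1)[None]
        if key_mask is not None:
            scores = np.where(key_mask[:, None, None, :], scores, self.NEG)
        if self.causal:
            causal = np.tril(np.ones((L, L), dtype=bool))
            scores = np.where(causal[None, None], scores, self.NEG)
        attn = _softmax(scores)
        ctx = attn @ v
        out = self.wo.forward(self._merge(ctx))
        self._cache = (q, k, v, attn, rel_idx)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        q, k, v, attn, rel_idx = self._cache
        g_ctx = self._split(self.wo.backward(g))
        g_attn = g_ctx @ v.transpose(0, 1, 3, 2)
        g_v = attn.transpose(0, 1, 3, 2) @ g_ctx
        # softmax backward (masked scores get zero grad automatically because
        # their attn weights are ~0)
        g_scores = attn * (g_attn - (g_attn * attn).sum(axis=-1, keepdims=True))
        if self.radius > 0:
            per_head = g_scores.sum(axis=0)  # (H, L, L)
            np.add.at(self.rel_bias.grad, rel_idx,
                      per_head.transpose(1, 2, 0))
        g_scores = g_scores / np.sqrt(self.dh)
        g_q = g_scores @ k
        g_k = g_scores.transpose(0, 1, 3, 2) @ q
        return (self.wq.backward(self._merge(g_q))
                + self.wk.backward(self._merge(g_k))
                + self.wv.backward(self._merge(g_v)))


class FeedForward(Module):
    def __init__(self, d: int, d_ff: int, rng: np.random.Generator):
        self.fc1 = Dense(d, d_ff, rng)
        self.act = GELU()
        self.fc2 = Dense(d_ff, d, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.fc2.forward(self.act.forward(self.fc1.forward(x)))

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.fc1.backward(self.act.backward(self.fc2.backward(g)))


class TransformerBlock(Module):
    """Pre-LN block: x + Attn(LN(x)), then x + FF(LN(x))."""

    def __init__(self, d: int, heads: int, d_ff: int, rng: np.random.Generator,
                 relative_bias_radius: int = 0, causal: bool = False):
        self.ln1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(
            d, heads, rng, relative_bias_radius=relative_bias_radius, causal=causal)
        self.ln2 = LayerNorm(d)
        self.ff = FeedForward(d, d_ff, rng)

    def forward(self, x: np.ndarray, key_mask: np.ndarray | None = None) -> np.ndarray:
        h = x + self.attn.forward(self.ln1.forward(x), key_mask)
        return h + self.ff.forward(self.ln2.forward(h))

    def backward(self, g: np.ndarray) -> np.ndarray:
        g_h = g + self.ln2.backward(self.ff.backward(g))
        return g_h + self.ln1.backward(self.attn.backward(g_h))


class AdamW:
    """AdamW with decoupled weight decay; lr is set per step by the caller."""

    def __init__(self, module: Module, lr: float = 5e-5, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.module = module
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {k: np.zeros_like(p.value) for k, p in module.parameters()}
        self._v = {k: np.zeros_like(p.value) for k, p in module.parameters()}

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for k, p in self.module.parameters():
            m = self._m[k] = self.b1 * self._m[k] + (1 - self.b1) * p.grad
            v = self._v[k] = self.b2 * self._v[k] + (1 - self.b2) * p.grad ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.value -= lr * (mhat / (np.sqrt(vhat) + self.eps)
                             + self.weight_decay * p.value)


def linear_warmup_decay(step: int, total_steps: int, peak_lr: float,
                        warmup_fraction: float = 0.1) -> float:
    """LR that scales linearly 0 -> peak over the warmup, then back to 0."""
    warmup = max(1, int(round(total_steps * warmup_fraction)))
    if step < warmup:
        return peak_lr * (step + 1) / warmup
    remaining = max(1, total_steps - warmup)
    return peak_lr * max(0.0, 1.0 - (step + 1 - warmup) / remaining)
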