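"""Neural-network building blocks on top of :mod:`pairedvae.autodiff`.

Layers follow the conventions of the mainstream deep-learning frameworks:
``Module`` objects own ``Parameter`` leaves, expose ``train()``/``eval()``
modes (batch normalisation uses batch statistics in train mode and running
statistics in eval mode), and are collected recursively for the optimizer.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, softmax

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "BatchNorm1d",
    "MultiHeadSelfAttention",
    "Adam",
    "clip_grad_norm",
]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)
        self.requires_grad = True  # parameters stay trainable even under no_grad at build time


class Module:
    """Base class with recursive parameter collection and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            for p in _collect(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in self.__dict__.values():
            for m in _collect_modules(v):
                mods.extend(m.modules())
        return mods

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # checkpointing -----------------------------------------------------------
    def state_dict(self) -> dict:
        state = {}
        for i, p in enumerate(self.parameters()):
            state[f"param_{i}"] = p.data
        for j, (m, name, buf) in enumerate(self._buffers()):
            state[f"buffer_{j}"] = buf
        return state

    def load_state_dict(self, state: dict):
        for i, p in enumerate(self.parameters()):
            arr = np.asarray(state[f"param_{i}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"checkpoint shape mismatch for param_{i}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype, copy=True)
        for j, (m, name, _) in enumerate(self._buffers()):
            setattr(m, name, np.asarray(state[f"buffer_{j}"]).copy())

    def _buffers(self):
        out = []
        for m in self.modules():
            for name in getattr(m, "_buffer_names", ()):
                out.append((m, name, getattr(m, name)))
        return out


def _collect(v):
    if isinstance(v, Parameter):
        yield v
    elif isinstance(v, Module):
        yield from v.parameters()
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _collect(item)


def _collect_modules(v):
    if isinstance(v, Module):
        yield v
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _collect_modules(item)


class Linear(Module):
    """Affine map ``x @ W + b`` with Glorot-uniform initialisation."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True,
                 dtype=np.float32):
        super().__init__()
        limit = np.sqrt(6.0 / (in_dim + out_dim))
        self.W = Parameter(rng.uniform(-limit, limit, size=(in_dim, out_dim)).astype(dtype))
        self.b = Parameter(np.zeros(out_dim, dtype=dtype)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class LayerNorm(Module):
    """Per-sample normalisation over the last axis, with learned gain/bias."""

    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=dtype))
        self.beta = Parameter(np.zeros(dim, dtype=dtype))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta


class BatchNorm1d(Module):
    """Batch normalisation over axis 0 with running statistics for eval mode."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, dim: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=dtype))
        self.beta = Parameter(np.zeros(dim, dtype=dtype))
        self.running_mean = np.zeros(dim, dtype=dtype)
        self.running_var = np.ones(dim, dtype=dtype)
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            n = x.shape[0]
            unbiased = var.data * (n / max(n - 1, 1))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel()).astype(self.running_mean.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased.ravel()).astype(self.running_var.dtype)
            xhat = xc / (var + self.eps).sqrt()
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over groups of hidden units.

    A cell's hidden vector of width ``n_heads * head_dim`` is viewed as a
    sequence of ``width / head_dim`` tokens of ``head_dim`` features.  Each
    head projects queries, keys and values per token, attends across the
    tokens, and the concatenated heads are projected back to ``head_dim``
    per token, so the output width equals the input width.
    """

    def __init__(self, width: int, n_heads: int, head_dim: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        if n_heads * head_dim != width:
            raise ValueError(f"n_heads*head_dim ({n_heads}*{head_dim}) must equal width {width}")
        if width % head_dim != 0:
            raise ValueError("width must be divisible by head_dim")
        self.width = width
        self.n_heads = n_heads
        self.head_dim = head_dim
        self.n_tokens = width // head_dim
        scale = 1.0 / np.sqrt(head_dim)
        shape = (n_heads, head_dim, head_dim)
        self.Wq = Parameter((rng.standard_normal(shape) * scale).astype(dtype))
        self.Wk = Parameter((rng.standard_normal(shape) * scale).astype(dtype))
        self.Wv = Parameter((rng.standard_normal(shape) * scale).astype(dtype))
        self.Wo = Parameter((rng.standard_normal((n_heads * head_dim, head_dim)) * scale).astype(dtype))

    def __call__(self, h: Tensor) -> Tensor:
        B = h.shape[0]
        T, d, H = self.n_tokens, self.head_dim, self.n_heads
        x = h.reshape(B, 1, T, d)                    # broadcast over heads
        q = x @ self.Wq                              # (B, H, T, d)
        k = x @ self.Wk
        v = x @ self.Wv
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d))   # (B, H, T, T)
        attn = softmax(scores, axis=-1)
        out = attn @ v                               # (B, H, T, d)
        out = out.transpose(0, 2, 1, 3).reshape(B, T, H * d)     # concat heads per token
        out = out @ self.Wo                          # (B, T, d)
        return out.reshape(B, T * d)

    def attention_weights(self, h: Tensor) -> np.ndarray:
        """Attention matrices (B, H, T, T) — diagnostics only."""
        B = h.shape[0]
        T, d = self.n_tokens, self.head_dim
        x = h.reshape(B, 1, T, d)
        q = (x @ self.Wq).data
        k = (x @ self.Wk).data
        scores = (q @ np.swapaxes(k, -1, -2)) / np.sqrt(d)
        e = np.exp(scores - scores.max(axis=-1, keepdims=True))
        return e / e.sum(axis=-1, keepdims=True)


class Adam:
    """Adam optimizer (Kingma & Ba) with optional global-norm gradient clipping."""

    def __init__(self, params: list[Parameter], lr: float = 5e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, clip_norm: float | None = None):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        if self.clip_norm is not None:
            clip_grad_norm(self.params, self.clip_norm)
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * (g * g)
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float(np.sum(p.grad.astype(np.float64) ** 2))
    norm = np.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm
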