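"""Neural-network building blocks on top of the autograd engine.

Modules follow the familiar container pattern: ``parameters()`` walks the
attribute tree, ``state_dict()`` / ``load_state_dict()`` serialize weights by
dotted name, and ``train()`` / ``eval()`` toggle stochastic layers.  Weight
initialization is fully determined by the ``numpy`` Generator handed to each
constructor, so models are reproducible from a seed.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autograd import Tensor, concatenate

__all__ = [
    "Module", "Linear", "LayerNorm", "Dropout", "Conv1d",
    "MultiheadSelfAttention", "TransformerBlock", "Sequential", "conv1d",
]


class Module:
    """Base class: attribute-tree parameter discovery and (de)serialization."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, "
                           f"unexpected={sorted(extra)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for value in vars(self).values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _param(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    scale = 1.0 / math.sqrt(fan_in)
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = _param(rng, (in_features, out_features), in_features)
        self.bias = _param(rng, (out_features,), in_features) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered / (var + self.eps).sqrt()
        return normed * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode.

    Draws its mask from a private Generator so training runs are reproducible
    from the model seed.
    """

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self._rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self._rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None, padding: int) -> Tensor:
    """1-D convolution, stride 1.

    ``x``: (B, C_in, T); ``weight``: (C_out, C_in, k); output (B, C_out, T_out)
    with T_out = T + 2*padding - k + 1.  Implemented as a dedicated autograd
    primitive (im2col forward, scatter-add backward) because strided views do
    not compose with the generic ops.
    """
    xd = x.data
    wd = weight.data
    k = wd.shape[2]
    if padding:
        xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding)))
    else:
        xp = xd
    cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # B,Cin,Tout,k
    out = np.einsum("bcts,ocs->bot", cols, wd, optimize=True)
    if bias is not None:
        out = out + bias.data[None, :, None]
    t_out = out.shape[2]

    parents = [p for p in (x, weight, bias) if p is not None and p.requires_grad]

    def backward(g: np.ndarray) -> None:
        if weight.requires_grad:
            gw = np.einsum("bcts,bot->ocs", cols, g, optimize=True)
            weight._accumulate(gw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for s in range(k):
                gxp[:, :, s:s + t_out] += np.einsum("bot,oc->bct", g, wd[:, :, s],
                                                    optimize=True)
            gx = gxp[:, :, padding:gxp.shape[2] - padding] if padding else gxp
            x._accumulate(gx)

    req = bool(parents)
    return Tensor(out, requires_grad=req, _parents=parents,
                  _backward=backward if req else None, _op="conv1d")


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int | str = "same",
                 bias: bool = True):
        super().__init__()
        if padding == "same":
            if kernel_size % 2 == 0:
                raise ValueError("'same' padding requires an odd kernel size")
            padding = kernel_size // 2
        self.padding = int(padding)
        fan_in = in_channels * kernel_size
        self.weight = _param(rng, (out_channels, in_channels, kernel_size), fan_in)
        self.bias = _param(rng, (out_channels,), fan_in) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.padding)


class MultiheadSelfAttention(Module):
    """Standard scaled dot-product self-attention.

    Scores are ``softmax(Q K^T / sqrt(d_head))``; the weights multiply the
    value projections.  The attention weights of the most recent forward pass
    are cached on ``last_attention`` (B, heads, T, T) for inspection.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)
        self.last_attention: np.ndarray | None = None

    def _split(self, t: Tensor, B: int, T: int) -> Tensor:
        return t.reshape(B, T, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        q = self._split(self.q_proj(x), B, T)
        k = self._split(self.k_proj(x), B, T)
        v = self._split(self.v_proj(x), B, T)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.d_head))
        attn = scores.softmax(axis=-1)
        self.last_attention = attn.data
        ctx = attn @ v  # B,h,T,dh
        merged = ctx.transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.out_proj(merged)


class TransformerBlock(Module):
    """Pre-norm transformer encoder block."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int,
                 rng: np.random.Generator, dropout: float = 0.1):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = MultiheadSelfAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.drop(self.attn(self.norm1(x)))
        x = x + self.drop(self.ff2(self.ff1(self.norm2(x)).gelu()))
        return x


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
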