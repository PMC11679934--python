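"""Trainable components of the representation-learning framework.

The processing chain:

1.  **Tokenizer** — raw windows (C, T) are cut into non-overlapping patches
    of ``patch_len`` samples (right-edge zero padding), linearly projected to
    ``d_model`` and given learned positional embeddings.
2.  **Encoder** — a stack of pre-norm transformer blocks; the outputs of the
    last ``k_layers_extracted`` blocks are collected as a layer-feature
    stack (defaults: 3 blocks, width 128, k = 3).
3.  **Aggregation** — the stack members are concatenated channel-wise,
    passed through multi-head self-attention (attention weights multiply the
    value projections), and reduced back to ``d_agg`` by two convolution
    layers: the fused mid-level feature.
4.  **Decoder** — convolution blocks followed by an MLP map aggregated
    features back to the signal domain for masked reconstruction.
5.  **Pyramid + fusion** — three convolution blocks narrow the channel width
    (256 -> 128 -> 64 under defaults); their outputs are concatenated
    (448 channels) and a 1x1 "SeqConv" filters them channel-wise down to the
    final 64-channel contrastive embedding, mean-pooled over time.
6.  **Classifier** — a single dense layer over the pooled embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from .nn import (Conv1d, Dropout, Linear, Module, MultiheadSelfAttention,
                 Tensor, TransformerBlock, concatenate)

__all__ = ["EncoderConfig", "Tokenizer", "TransformerEncoder", "Aggregator",
           "Decoder", "Pyramid", "Fusion", "Classifier", "ModelBundle",
           "LayerFeatureStack", "AggregatedFeature", "PyramidFeatures"]


@dataclass
class EncoderConfig:
    """Architecture hyperparameters (defaults: 3 encoder blocks of width
    128; pyramid widths 256/128/64; 64-channel fused embedding)."""

    d_model: int = 128
    n_blocks: int = 3
    n_heads: int = 4
    ff_dim: int = 256
    patch_len: int = 25
    k_layers_extracted: int = 3
    d_agg: int = 128                   # width after the two reduction convs
    dropout: float = 0.1
    decoder_dim: int = 128
    pyramid_dims: tuple[int, int, int] = (256, 128, 64)
    latent_dim: int = 64
    n_classes: int = 5

    def __post_init__(self) -> None:
        if self.k_layers_extracted > self.n_blocks:
            raise ValueError(f"k_layers_extracted ({self.k_layers_extracted}) "
                             f"exceeds n_blocks ({self.n_blocks})")
        if len(self.pyramid_dims) != 3:
            raise ValueError("pyramid_dims must have exactly three widths")
        if not (self.pyramid_dims[0] > self.pyramid_dims[1] > self.pyramid_dims[2]):
            raise ValueError("pyramid widths must be strictly decreasing, "
                             f"got {self.pyramid_dims}")

    def n_tokens(self, n_timesteps: int) -> int:
        if self.patch_len > n_timesteps:
            raise ValueError(f"patch_len ({self.patch_len}) exceeds "
                             f"n_timesteps ({n_timesteps})")
        return -(-n_timesteps // self.patch_len)


@dataclass
class LayerFeatureStack:
    """Per-layer encoder outputs, one (B, tokens, d_model) array per
    extracted block, in depth order."""

    layers: list[Tensor]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("layer feature stack is empty")
        shapes = {tuple(t.shape) for t in self.layers}
        if len(shapes) != 1:
            raise ValueError(f"stack members differ in shape: {shapes}")

    def __len__(self) -> int:
        return len(self.layers)

    def concat(self) -> Tensor:
        """Channel-wise concatenation: (B, tokens, k * d_model)."""
        return concatenate(self.layers, axis=-1)


@dataclass
class AggregatedFeature:
    features: Tensor                  # (B, tokens, d_agg)
    attention_weights: np.ndarray     # (B, heads, tokens, tokens); rows sum to 1


@dataclass
class PyramidFeatures:
    cf1: Tensor                       # (B, 256, tokens) under defaults
    cf2: Tensor                       # (B, 128, tokens)
    cf3: Tensor                       # (B, 64, tokens)


class Tokenizer(Module):
    """Patchify + linear projection + learned positional embedding.

    A patch spans all channels, so multi-channel inputs are mixed at the
    projection.  The last patch is zero-padded when T is not a multiple of
    ``patch_len``.
    """

    def __init__(self, n_channels: int, n_timesteps: int, cfg: EncoderConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.n_channels = n_channels
        self.n_timesteps = n_timesteps
        self.patch_len = cfg.patch_len
        self.n_tok = cfg.n_tokens(n_timesteps)
        self.proj = Linear(n_channels * cfg.patch_len, cfg.d_model, rng)
        self.pos = Tensor(0.02 * rng.standard_normal((self.n_tok, cfg.d_model)),
                          requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        B, C, T = x.shape
        if C != self.n_channels or T != self.n_timesteps:
            raise ValueError(f"expected ({self.n_channels}, {self.n_timesteps}) "
                             f"windows, got ({C}, {T})")
        pad = self.n_tok * self.patch_len - T
        if pad:
            xd = np.concatenate([x.data, np.zeros((B, C, pad))], axis=2)
            x = Tensor._make(xd, (x,), lambda g, _x=x, _T=T: _x._accumulate(
                g[:, :, :_T]), "pad")
        # (B, C, n_tok, patch) -> (B, n_tok, C * patch)
        patches = x.reshape(B, C, self.n_tok, self.patch_len) \
                   .transpose(0, 2, 1, 3).reshape(B, self.n_tok,
                                                  C * self.patch_len)
        return self.proj(patches) + self.pos


class TransformerEncoder(Module):
    """Stacked transformer blocks; collects the last k block outputs."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.blocks = [TransformerBlock(cfg.d_model, cfg.n_heads, cfg.ff_dim,
                                        rng, cfg.dropout)
                       for _ in range(cfg.n_blocks)]
        self.k = cfg.k_layers_extracted

    def forward(self, tokens: Tensor) -> LayerFeatureStack:
        if not np.all(np.isfinite(tokens.data)):
            raise ValueError("encoder input contains non-finite values")
        outputs = []
        x = tokens
        for block in self.blocks:
            x = block(x)
            outputs.append(x)
        return LayerFeatureStack(outputs[-self.k:])


class Aggregator(Module):
    """Attention-based fusion of the layer-feature stack.

    Concatenates the k per-layer features channel-wise, applies multi-head
    self-attention over the concatenation, and narrows the width back to
    ``d_agg`` with two 1-D convolutions over the channel dimension.
    """

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        wide = cfg.k_layers_extracted * cfg.d_model
        heads = cfg.n_heads if wide % cfg.n_heads == 0 else 1
        self.attn = MultiheadSelfAttention(wide, heads, rng)
        mid = (wide + cfg.d_agg) // 2
        self.reduce1 = Conv1d(wide, mid, kernel_size=1, rng=rng)
        self.reduce2 = Conv1d(mid, cfg.d_agg, kernel_size=1, rng=rng)
        self.drop = Dropout(cfg.dropout, rng)

    def forward(self, stack: LayerFeatureStack) -> AggregatedFeature:
        wide = stack.concat()                       # (B, T, k*d)
        attended = self.drop(self.attn(wide))       # weights times values
        x = attended.transpose(0, 2, 1)             # (B, k*d, T)
        x = self.reduce1(x).relu()
        x = self.reduce2(x)
        return AggregatedFeature(x.transpose(0, 2, 1),
                                 self.attn.last_attention)


class Decoder(Module):
    """Reconstruction head: convolution blocks then per-token MLP back to
    patch space, reassembled into a (C, T) window."""

    def __init__(self, n_channels: int, n_timesteps: int, cfg: EncoderConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.n_channels = n_channels
        self.n_timesteps = n_timesteps
        self.patch_len = cfg.patch_len
        self.n_tok = cfg.n_tokens(n_timesteps)
        d = cfg.decoder_dim
        self.conv1 = Conv1d(cfg.d_agg, d, kernel_size=3, rng=rng)
        self.conv2 = Conv1d(d, d, kernel_size=3, rng=rng)
        self.mlp1 = Linear(d, d, rng)
        self.mlp2 = Linear(d, n_channels * cfg.patch_len, rng)

    def forward(self, agg: AggregatedFeature) -> Tensor:
        x = agg.features.transpose(0, 2, 1)         # (B, d_agg, T_tok)
        x = self.conv1(x).relu()
        x = self.conv2(x).relu()
        x = x.transpose(0, 2, 1)                    # (B, T_tok, d)
        x = self.mlp2(self.mlp1(x).relu())          # (B, T_tok, C*patch)
        B = x.shape[0]
        x = x.reshape(B, self.n_tok, self.n_channels, self.patch_len) \
             .transpose(0, 2, 1, 3) \
             .reshape(B, self.n_channels, self.n_tok * self.patch_len)
        return x[:, :, :self.n_timesteps]


class Pyramid(Module):
    """Three sequential convolution blocks with decreasing channel width."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        d1, d2, d3 = cfg.pyramid_dims
        self.conv1 = Conv1d(cfg.d_agg, d1, kernel_size=3, rng=rng)
        self.conv2 = Conv1d(d1, d2, kernel_size=3, rng=rng)
        self.conv3 = Conv1d(d2, d3, kernel_size=3, rng=rng)

    def forward(self, agg: AggregatedFeature) -> PyramidFeatures:
        x = agg.features.transpose(0, 2, 1)         # (B, d_agg, T_tok)
        cf1 = self.conv1(x).relu()
        cf2 = self.conv2(cf1).relu()
        cf3 = self.conv3(cf2).relu()
        return PyramidFeatures(cf1, cf2, cf3)


class Fusion(Module):
    """Channel-wise concatenation of the pyramid outputs followed by a 1x1
    convolution ("SeqConv") filtering down to the latent width, then mean
    pooling over time."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        total = sum(cfg.pyramid_dims)
        self.seq_conv = Conv1d(total, cfg.latent_dim, kernel_size=1, rng=rng)

    def forward(self, p: PyramidFeatures) -> Tensor:
        stacked = concatenate([p.cf1, p.cf2, p.cf3], axis=1)   # (B, 448, T)
        z = self.seq_conv(stacked)                             # (B, 64, T)
        return z.mean(axis=2)                                  # (B, 64)


class Classifier(Module):
    """Final dense layer over the latent embedding."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        if cfg.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {cfg.n_classes}")
        self.dense = Linear(cfg.latent_dim, cfg.n_classes, rng)

    def forward(self, z: Tensor) -> Tensor:
        return self.dense(z)


class ModelBundle(Module):
    """All components for one dataset geometry, built from a single seed."""

    def __init__(self, n_channels: int, n_timesteps: int, cfg: EncoderConfig,
                 seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.n_channels = n_channels
        self.n_timesteps = n_timesteps
        rng = np.random.default_rng(seed)
        self.tokenizer = Tokenizer(n_channels, n_timesteps, cfg, rng)
        self.encoder = TransformerEncoder(cfg, rng)
        self.aggregator = Aggregator(cfg, rng)
        self.decoder = Decoder(n_channels, n_timesteps, cfg, rng)
        self.pyramid = Pyramid(cfg, rng)
        self.fusion = Fusion(cfg, rng)
        self.classifier = Classifier(cfg, rng)

    # convenience chains -------------------------------------------------
    def encode(self, x: Tensor) -> LayerFeatureStack:
        return self.encoder(self.tokenizer(x))

    def aggregate(self, x: Tensor) -> AggregatedFeature:
        return self.aggregator(self.encode(x))

    def reconstruct(self, x: Tensor) -> Tensor:
        return self.decoder(self.aggregate(x))

    def embed(self, x: Tensor, detach_backbone: bool = False) -> Tensor:
        agg = self.aggregate(x)
        if detach_backbone:
            agg = AggregatedFeature(agg.features.detach(),
                                    agg.attention_weights)
        return self.fusion(self.pyramid(agg))

    def logits(self, x: Tensor, detach_backbone: bool = False) -> Tensor:
        return self.classifier(self.embed(x, detach_backbone))

    # component parameter groups -----------------------------------------
    def backbone_modules(self) -> dict[str, Module]:
        return {"tokenizer": self.tokenizer, "encoder": self.encoder,
                "aggregator": self.aggregator}

    def refinement_modules(self) -> dict[str, Module]:
        return {"pyramid": self.pyramid, "fusion": self.fusion}
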