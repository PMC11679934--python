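"""Time-domain augmentations, block masking, and pre-training view assembly.

Two augmentation strengths produce the contrasted views: the *strong* view
applies permutation, jitter and scaling (each independently with probability
``p_apply``), the *weak* view applies a gentle "scale-jitter" (small scale
factor composed with low-sigma jitter).  Masking zeroes contiguous blocks of
timesteps — exactly ``round(mask_ratio * T)`` positions arranged in
``n_mask_blocks`` runs — so that the reconstruction network must infer the
missing segments from context rather than interpolate isolated points.
Masking is applied on top of the time-augmented signal, so each view batch
carries, per sample: the original, the strong and weak augmented views, and
K masked variants of each view.  With N originals that makes 2N(K+1)
distinct signals available to the contrastive stage.

Mask *positions* are drawn uniformly at random by default; ``sample_mask``
accepts a pluggable position sampler so a learned placement policy can be
swapped in without touching the batch assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["AugmentationConfig", "MaskSpec", "ViewBatch", "jitter", "scale",
           "permute", "shift", "strong_augment", "weak_augment",
           "sample_mask", "apply_mask", "build_view_batch"]


@dataclass
class AugmentationConfig:
    """Augmentation parameters; defaults follow the benchmark protocol
    (50% application probability, scaling in [0.5, 1.5], jitter sigma in
    [0, 0.8], 5 permutation segments, masking ratio 0.25)."""

    p_apply: float = 0.5
    scale_range: tuple[float, float] = (0.5, 1.5)
    jitter_sigma_range: tuple[float, float] = (0.0, 0.8)
    n_permute_segments: int = 5
    mask_ratio: float = 0.25
    n_mask_blocks: int = 3
    n_masked_versions: int = 1          # K masked variants per view
    mask_fill: float = 0.0              # fill value; 0 = mean of z-scored data
    weak_scale_range: tuple[float, float] = (0.9, 1.1)
    weak_jitter_sigma: float = 0.1
    enable_shift: bool = False          # circular time shift (off by default)
    max_shift_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_apply <= 1.0:
            raise ValueError(f"p_apply must be in [0,1], got {self.p_apply}")
        if not 0.0 <= self.mask_ratio < 1.0:
            raise ValueError(f"mask_ratio must be in [0,1), got {self.mask_ratio}")
        if self.n_mask_blocks < 1:
            raise ValueError(f"n_mask_blocks must be positive, got {self.n_mask_blocks}")
        if self.n_masked_versions < 1:
            raise ValueError("n_masked_versions must be positive, "
                             f"got {self.n_masked_versions}")
        if self.n_permute_segments < 1:
            raise ValueError("n_permute_segments must be positive, "
                             f"got {self.n_permute_segments}")
        if self.jitter_sigma_range[0] < 0:
            raise ValueError("jitter sigma must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class MaskSpec:
    """Boolean keep-mask over timesteps; True = keep, False = masked."""

    keep_flags: np.ndarray
    ratio_actual: float

    @property
    def n_masked(self) -> int:
        return int((~self.keep_flags).sum())

    @property
    def n_runs(self) -> int:
        """Number of contiguous masked runs."""
        m = (~self.keep_flags).astype(int)
        return int(np.sum(np.diff(np.concatenate([[0], m])) == 1))


@dataclass
class ViewBatch:
    """Paired augmented views, their masked variants, and the originals."""

    originals: np.ndarray       # (N, C, T)
    strong_views: np.ndarray    # (N, C, T)
    weak_views: np.ndarray      # (N, C, T)
    masked_strong: np.ndarray   # (N, K, C, T)
    masked_weak: np.ndarray     # (N, K, C, T)
    mask_specs_strong: list = field(default_factory=list)   # N lists of K MaskSpec
    mask_specs_weak: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.originals.shape[0]

    @property
    def n_masked_versions(self) -> int:
        return self.masked_strong.shape[1]

    @property
    def masked_views(self) -> np.ndarray:
        """Masked variants of the strong view, flattened to (N*K, C, T)."""
        N, K, C, T = self.masked_strong.shape
        return self.masked_strong.reshape(N * K, C, T)

    @property
    def n_contrastive_signals(self) -> int:
        """Total distinct signals for the contrastive stage: 2N(K+1)."""
        return 2 * self.n_samples * (self.n_masked_versions + 1)


# ----------------------------------------------------------- primitive ops

def jitter(x: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Add zero-mean Gaussian noise of scale ``sigma``."""
    if sigma < 0:
        raise ValueError(f"jitter sigma must be nonnegative, got {sigma}")
    if sigma == 0:
        return x.copy()
    return x + rng.normal(0.0, sigma, size=x.shape)


def scale(x: np.ndarray, factor: float) -> np.ndarray:
    """Multiply every element by ``factor``."""
    return x * factor


def permute(x: np.ndarray, n_segments: int, rng: np.random.Generator) -> np.ndarray:
    """Cut the time axis into ``n_segments`` at random interior points and
    reorder the segments; preserves the per-channel value multiset."""
    T = x.shape[-1]
    if n_segments > T:
        raise ValueError(f"n_segments ({n_segments}) exceeds n_timesteps ({T})")
    if n_segments == 1:
        return x.copy()
    splits = np.sort(rng.choice(np.arange(1, T), size=n_segments - 1,
                                replace=False))
    segments = np.split(x, splits, axis=-1)
    order = rng.permutation(n_segments)
    return np.concatenate([segments[i] for i in order], axis=-1)


def shift(x: np.ndarray, max_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Circular shift along time by up to ``max_fraction`` of the window."""
    T = x.shape[-1]
    amount = int(rng.integers(-int(max_fraction * T), int(max_fraction * T) + 1))
    return np.roll(x, amount, axis=-1)


def strong_augment(x: np.ndarray, cfg: AugmentationConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Permutation, jitter and scaling, each applied with prob ``p_apply``."""
    out = x.copy()
    if rng.random() < cfg.p_apply:
        out = permute(out, cfg.n_permute_segments, rng)
    if cfg.enable_shift and rng.random() < cfg.p_apply:
        out = shift(out, cfg.max_shift_fraction, rng)
    if rng.random() < cfg.p_apply:
        sigma = rng.uniform(*cfg.jitter_sigma_range)
        out = jitter(out, sigma, rng)
    if rng.random() < cfg.p_apply:
        out = scale(out, rng.uniform(*cfg.scale_range))
    return out


def weak_augment(x: np.ndarray, cfg: AugmentationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Scale-jitter: gentle scaling composed with low-sigma jitter."""
    out = x.copy()
    if rng.random() < cfg.p_apply:
        out = scale(out, rng.uniform(*cfg.weak_scale_range))
        out = jitter(out, rng.uniform(0.0, cfg.weak_jitter_sigma), rng)
    return out


# ---------------------------------------------------------------- masking

def _block_lengths(total: int, n_blocks: int, T: int) -> list[int]:
    """Split ``total`` masked positions into contiguous runs.

    Runs share the ceiling length; the last run takes the remainder (and may
    be shorter).  The run count shrinks when ``total`` or the free space
    cannot support ``n_blocks`` separated runs.
    """
    n_runs = min(n_blocks, total)
    while n_runs > 1:
        L = -(-total // n_runs)  # ceil
        last = total - L * (n_runs - 1)
        if last >= 1 and total + (n_runs - 1) <= T:
            break
        n_runs -= 1
    if n_runs == 1:
        return [total]
    L = -(-total // n_runs)
    return [L] * (n_runs - 1) + [total - L * (n_runs - 1)]


def sample_mask(n_timesteps: int, cfg: AugmentationConfig,
                rng: np.random.Generator,
                position_sampler: Callable[..., np.ndarray] | None = None,
                ) -> MaskSpec:
    """Draw a block mask: exactly ``round(mask_ratio * T)`` masked positions
    in ``n_mask_blocks`` contiguous runs with uniformly random placement.

    ``position_sampler``, if given, overrides placement: it is called as
    ``position_sampler(n_timesteps, cfg, rng)`` and must return a boolean
    keep array (hook for learned mask placement).
    """
    total = int(round(cfg.mask_ratio * n_timesteps))
    if total > n_timesteps:
        raise ValueError(f"masked count {total} exceeds n_timesteps {n_timesteps}")
    if position_sampler is not None:
        keep = np.asarray(position_sampler(n_timesteps, cfg, rng), dtype=bool)
        if keep.shape != (n_timesteps,):
            raise ValueError("position_sampler must return a length-T boolean array")
        return MaskSpec(keep, float((~keep).sum()) / n_timesteps)
    keep = np.ones(n_timesteps, dtype=bool)
    if total == 0:
        return MaskSpec(keep, 0.0)
    lengths = _block_lengths(total, cfg.n_mask_blocks, n_timesteps)
    n_runs = len(lengths)
    # stars-and-bars: distribute the free space uniformly among the gaps
    # before/between/after runs, with at least one kept sample between runs
    free = n_timesteps - total - (n_runs - 1)
    cuts = np.sort(rng.choice(free + n_runs, size=n_runs, replace=False))
    extra = cuts - np.arange(n_runs)          # nondecreasing extra gap offsets
    pos = 0
    consumed = 0
    for i, L in enumerate(lengths):
        gap = int(extra[i]) - (int(extra[i - 1]) if i else 0)
        pos += gap + (1 if i else 0)          # interior separator of >= 1
        keep[pos:pos + L] = False
        pos += L
        consumed += L
    return MaskSpec(keep, total / n_timesteps)


def apply_mask(x: np.ndarray, mask: MaskSpec, fill: float = 0.0) -> np.ndarray:
    """Set masked positions to ``fill``; unmasked positions are untouched."""
    if mask.keep_flags.shape[0] != x.shape[-1]:
        raise ValueError(f"mask length {mask.keep_flags.shape[0]} does not "
                         f"match n_timesteps {x.shape[-1]}")
    out = x.copy()
    out[..., ~mask.keep_flags] = fill
    return out


# ------------------------------------------------------------- batch build

def build_view_batch(originals: np.ndarray, cfg: AugmentationConfig,
                     rng: np.random.Generator) -> ViewBatch:
    """Assemble a pre-training batch: strong/weak views plus K masked
    variants of each view (masking applied after time augmentation)."""
    originals = np.asarray(originals, dtype=np.float64)
    if originals.ndim != 3 or originals.shape[0] == 0:
        raise ValueError("originals must be a non-empty (N, C, T) batch")
    N, C, T = originals.shape
    K = cfg.n_masked_versions
    strong = np.empty_like(originals)
    weak = np.empty_like(originals)
    masked_s = np.empty((N, K, C, T))
    masked_w = np.empty((N, K, C, T))
    specs_s: list[list[MaskSpec]] = []
    specs_w: list[list[MaskSpec]] = []
    for i in range(N):
        strong[i] = strong_augment(originals[i], cfg, rng)
        weak[i] = weak_augment(originals[i], cfg, rng)
        row_s, row_w = [], []
        for j in range(K):
            ms = sample_mask(T, cfg, rng)
            mw = sample_mask(T, cfg, rng)
            masked_s[i, j] = apply_mask(strong[i], ms, cfg.mask_fill)
            masked_w[i, j] = apply_mask(weak[i], mw, cfg.mask_fill)
            row_s.append(ms)
            row_w.append(mw)
        specs_s.append(row_s)
        specs_w.append(row_w)
    return ViewBatch(originals, strong, weak, masked_s, masked_w,
                     specs_s, specs_w)
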