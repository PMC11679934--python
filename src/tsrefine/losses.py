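"""Training objectives: reconstruction, pairwise KL constraint, and the
normalized temperature-scaled contrastive (NT-Xent) loss.

Pre-training minimizes ``reconstruction + gamma * pairwise``: the decoder
must reproduce the (time-augmented, unmasked) signal from its masked
version, while the pairwise term pulls the embedding of each masked variant
toward its source and away from other samples.  The pairwise term is a
Kullback-Leibler divergence between the anchor's similarity distribution
restricted to its positives and the full candidate distribution; minimizing
it aligns masked and unmasked representations.  The refinement stage uses
NT-Xent between the strong-view and weak-view embeddings.

All losses are means over anchors/samples so that the mixing weight gamma
is independent of batch size.  Similarities are cosine similarities divided
by a temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, as_tensor

__all__ = ["LossWeights", "reconstruction_loss", "pairwise_loss",
           "pretrain_loss", "cosine_similarity", "contrastive_loss"]

_EPS = 1e-12


@dataclass
class LossWeights:
    """gamma weights the pairwise term against reconstruction;
    temperatures scale the cosine-similarity logits."""

    gamma: float = 0.1
    temperature_pair: float = 0.2
    temperature_cl: float = 0.2
    auto_balance: bool = False   # rescale pairwise term to recon magnitude

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma must be nonnegative, got {self.gamma}")
        if self.temperature_pair <= 0 or self.temperature_cl <= 0:
            raise ValueError("temperatures must be positive")


def reconstruction_loss(x: Tensor | np.ndarray, xhat: Tensor | np.ndarray,
                        reduction: str = "mean") -> Tensor:
    """Squared L2 distance between signal and reconstruction.

    ``reduction='sum'`` sums over samples; ``'mean'`` (default) averages per
    batch element for scale stability.
    """
    x, xhat = as_tensor(x), as_tensor(xhat)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xhat.shape}")
    diff = x - xhat
    per_sample = (diff * diff).reshape(x.shape[0], -1).sum(axis=1)
    if reduction == "sum":
        return per_sample.sum()
    if reduction == "mean":
        return per_sample.mean()
    raise ValueError(f"unknown reduction {reduction!r}")


def _normalize_rows(z: Tensor) -> Tensor:
    norms = (z * z).sum(axis=1, keepdims=True).sqrt()
    if np.any(norms.data < _EPS):
        raise ValueError("zero-norm embedding; cosine similarity undefined")
    return z / norms


def cosine_similarity(u: Tensor | np.ndarray, v: Tensor | np.ndarray) -> float:
    """Standard cosine similarity of two vectors, in [-1, 1]."""
    u = np.asarray(u.data if isinstance(u, Tensor) else u, dtype=np.float64)
    v = np.asarray(v.data if isinstance(v, Tensor) else v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS or nv < _EPS:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(u @ v / (nu * nv))


def pairwise_loss(embeddings: Tensor, pair_index: np.ndarray,
                  temperature: float = 0.2) -> Tensor:
    """KL constraint between masked variants and their source signals.

    ``embeddings``: (M, D) rows for originals and masked versions together.
    ``pair_index``: length-M integer array mapping every row to its source
    sample id (an original maps to itself, a masked version to its source).
    Rows sharing a source id are positive pairs; all others are negatives.

    For each anchor, let q = softmax over all other rows of the cosine
    similarity / temperature, and p = the same softmax restricted to the
    anchor's positives.  The loss is the mean over anchors of KL(p || q),
    which is zero exactly when all mass of q sits on the positives.
    """
    pair_index = np.asarray(pair_index)
    M = embeddings.shape[0]
    if pair_index.shape != (M,):
        raise ValueError(f"pair_index must have length {M}")
    counts = {}
    for s in pair_index:
        counts[int(s)] = counts.get(int(s), 0) + 1
    if any(c < 2 for c in counts.values()):
        lonely = [s for s, c in counts.items() if c < 2]
        raise ValueError(f"sources with no positive partner: {lonely}")
    zn = _normalize_rows(embeddings)
    sim = (zn @ zn.transpose(1, 0)) * (1.0 / temperature)      # (M, M)
    same = pair_index[:, None] == pair_index[None, :]
    eye = np.eye(M, dtype=bool)
    pos_mask = same & ~eye
    cand_mask = ~eye
    neg_inf = -1e30
    # log q over all candidates; log p over positives only
    log_q = (sim + Tensor(np.where(cand_mask, 0.0, neg_inf))).log_softmax(axis=1)
    log_p = (sim + Tensor(np.where(pos_mask, 0.0, neg_inf))).log_softmax(axis=1)
    p = log_p.exp() * Tensor(pos_mask.astype(float))
    kl_rows = (p * (log_p - log_q) * Tensor(pos_mask.astype(float))).sum(axis=1)
    return kl_rows.mean()


def pretrain_loss(x: Tensor | np.ndarray, xhat: Tensor | np.ndarray,
                  embeddings: Tensor, pair_index: np.ndarray,
                  weights: LossWeights) -> tuple[Tensor, dict[str, float]]:
    """Weighted sum: reconstruction + gamma * pairwise.

    Returns the total loss and a dict of the component values.  With
    ``auto_balance`` the pairwise term is rescaled to the reconstruction
    term's magnitude before weighting.
    """
    rec = reconstruction_loss(x, xhat)
    pair = pairwise_loss(embeddings, pair_index, weights.temperature_pair)
    gamma = weights.gamma
    if weights.auto_balance and pair.item() > _EPS:
        gamma = weights.gamma * rec.item() / pair.item()
    total = rec + gamma * pair
    return total, {"reconstruction": rec.item(), "pairwise": pair.item(),
                   "gamma_effective": float(gamma)}


def contrastive_loss(z_strong: Tensor, z_weak: Tensor,
                     temperature: float = 0.2) -> Tensor:
    """NT-Xent between two views.

    Embeddings with the same index across the two batches form the positive
    pair; every other embedding from either view is a negative.  For each of
    the 2N anchors the loss is -log softmax(positive | all candidates except
    the anchor itself), with cosine similarities divided by ``temperature``;
    the mean over anchors is returned.
    """
    if z_strong.shape != z_weak.shape:
        raise ValueError(f"view shape mismatch: {z_strong.shape} vs "
                         f"{z_weak.shape}")
    N = z_strong.shape[0]
    if N < 2:
        raise ValueError("contrastive loss requires batch size >= 2 "
                         "(no negatives otherwise)")
    from .nn import concatenate
    z = _normalize_rows(concatenate([z_strong, z_weak], axis=0))   # (2N, D)
    sim = (z @ z.transpose(1, 0)) * (1.0 / temperature)
    eye = np.eye(2 * N, dtype=bool)
    log_q = (sim + Tensor(np.where(eye, -1e30, 0.0))).log_softmax(axis=1)
    pos_idx = np.concatenate([np.arange(N, 2 * N), np.arange(N)])
    picked = log_q[np.arange(2 * N), pos_idx]
    return -picked.mean()
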