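"""Loss functions vs independent literal-loop oracles and limit cases."""

import math

import numpy as np
import pytest

from tsrefine.losses import (LossWeights, contrastive_loss,
                             cosine_similarity, pairwise_loss,
                             pretrain_loss, reconstruction_loss)
from tsrefine.nn import Adam, Linear, Tensor


# ---------------------------------------------------------------- oracles

def cosine(u, v):
    return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))


def ntxent_bruteforce(z_strong, z_weak, temperature):
    """Literal double-sum evaluation: every anchor scored against every
    candidate except itself; positive = same sample index across views."""
    z = np.concatenate([z_strong, z_weak], axis=0)
    M = z.shape[0]
    N = M // 2
    losses = []
    for a in range(M):
        b = a + N if a < N else a - N   # the matched view of the same sample
        num = math.exp(cosine(z[a], z[b]) / temperature)
        den = sum(math.exp(cosine(z[a], z[t]) / temperature)
                  for t in range(M) if t != a)
        losses.append(-math.log(num / den))
    return float(np.mean(losses))


def pairwise_bruteforce(emb, pair_index, temperature):
    """Literal KL between the positive-restricted and full candidate
    distributions, averaged over anchors."""
    M = emb.shape[0]
    losses = []
    for a in range(M):
        sims = {t: cosine(emb[a], emb[t]) / temperature
                for t in range(M) if t != a}
        pos = [t for t in sims if pair_index[t] == pair_index[a]]
        zq = sum(math.exp(s) for s in sims.values())
        zp = sum(math.exp(sims[t]) for t in pos)
        kl = 0.0
        for t in pos:
            p = math.exp(sims[t]) / zp
            q = math.exp(sims[t]) / zq
            kl += p * math.log(p / q)
        losses.append(kl)
    return float(np.mean(losses))


# ----------------------------------------------------------- reconstruction

def test_reconstruction_identity_is_zero():
    x = np.random.default_rng(0).standard_normal((3, 2, 16))
    assert reconstruction_loss(x, x).item() == 0.0


def test_reconstruction_unit_difference_sums_elementwise():
    """Two length-4 windows differing by 1 everywhere: unreduced sum 4+4=8."""
    x = np.zeros((2, 1, 4))
    xhat = np.ones((2, 1, 4))
    assert reconstruction_loss(x, xhat, reduction="sum").item() == pytest.approx(8.0)
    assert reconstruction_loss(x, xhat).item() == pytest.approx(4.0)


def test_reconstruction_matches_naive_loop():
    rng = np.random.default_rng(7)
    x = rng.standard_normal((4, 3, 10))
    xhat = rng.standard_normal((4, 3, 10))
    naive = 0.0
    for i in range(4):
        for c in range(3):
            for t in range(10):
                naive += (x[i, c, t] - xhat[i, c, t]) ** 2
    assert reconstruction_loss(x, xhat, reduction="sum").item() == \
        pytest.approx(naive, abs=1e-10)


def test_reconstruction_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shape"):
        reconstruction_loss(np.zeros((2, 1, 4)), np.zeros((2, 1, 5)))


def test_reconstruction_is_squared_metric():
    rng = np.random.default_rng(1)
    a, b = rng.standard_normal((2, 5, 1, 8))
    ab = reconstruction_loss(a, b).item()
    assert ab > 0
    assert ab == pytest.approx(reconstruction_loss(b, a).item())


# ----------------------------------------------------------------- pairwise

@pytest.mark.parametrize("n,k,temp,seed", [
    (3, 1, 0.2, 0), (4, 2, 0.2, 1), (8, 1, 1.0, 2), (5, 2, 0.5, 3),
    (2, 1, 0.1, 4), (6, 2, 0.3, 5),
])
def test_pairwise_matches_bruteforce(n, k, temp, seed):
    rng = np.random.default_rng(seed)
    emb = rng.standard_normal((n * (k + 1), 8))
    pair_index = np.concatenate([np.arange(n), np.repeat(np.arange(n), k)])
    got = pairwise_loss(Tensor(emb), pair_index, temperature=temp).item()
    want = pairwise_bruteforce(emb, pair_index, temp)
    assert got == pytest.approx(want, abs=1e-8)


def test_pairwise_identical_embeddings_equals_log_candidate_count():
    """All-equal embeddings, one positive per anchor: both distributions
    are uniform on their supports and the KL reduces to log(M - 1)."""
    M = 6
    emb = np.ones((M, 4))
    pair_index = np.array([0, 1, 2, 0, 1, 2])
    got = pairwise_loss(Tensor(emb), pair_index, temperature=0.2).item()
    assert got == pytest.approx(math.log(M - 1), abs=1e-8)


def test_pairwise_separated_positives_drive_loss_to_zero():
    """When positives coincide and negatives are far, q concentrates on the
    positives and the KL vanishes."""
    emb = np.array([[100.0, 0], [0, 100.0], [100.0, 0.001], [0.001, 100.0]])
    pair_index = np.array([0, 1, 0, 1])
    got = pairwise_loss(Tensor(emb), pair_index, temperature=0.05).item()
    assert got < 1e-6


def test_pairwise_orphan_embedding_rejected():
    emb = np.ones((3, 4))
    with pytest.raises(ValueError, match="no positive"):
        pairwise_loss(Tensor(emb), np.array([0, 0, 5]))


# -------------------------------------------------------------- total loss

def test_pretrain_loss_gamma_zero_is_reconstruction():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((3, 1, 8))
    xhat = rng.standard_normal((3, 1, 8))
    emb = rng.standard_normal((6, 4))
    pi = np.array([0, 1, 2, 0, 1, 2])
    total, parts = pretrain_loss(x, xhat, Tensor(emb), pi,
                                 LossWeights(gamma=0.0))
    assert total.item() == pytest.approx(parts["reconstruction"])


def test_pretrain_loss_is_exact_weighted_sum_and_monotone_in_gamma():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((3, 1, 8))
    xhat = rng.standard_normal((3, 1, 8))
    emb = rng.standard_normal((6, 4))
    pi = np.array([0, 1, 2, 0, 1, 2])
    totals = []
    for gamma in (0.0, 0.5, 1.0, 2.0):
        total, parts = pretrain_loss(x, xhat, Tensor(emb), pi,
                                     LossWeights(gamma=gamma))
        assert total.item() == pytest.approx(
            parts["reconstruction"] + gamma * parts["pairwise"], abs=1e-10)
        totals.append(total.item())
    assert totals == sorted(totals)


# ------------------------------------------------------------------ cosine

def test_cosine_similarity_basic_identities():
    u = np.array([1.0, 2.0, -3.0])
    assert cosine_similarity(u, u) == pytest.approx(1.0)
    assert cosine_similarity(u, -u) == pytest.approx(-1.0)
    assert cosine_similarity(np.array([1.0, 0.0]),
                             np.array([0.0, 1.0])) == pytest.approx(0.0)
    with pytest.raises(ValueError, match="zero"):
        cosine_similarity(np.zeros(3), u)


# ------------------------------------------------------------- contrastive

@pytest.mark.parametrize("n,temp,seed", [
    (2, 0.2, 0), (4, 0.2, 1), (8, 1.0, 2), (5, 0.5, 3), (3, 0.1, 4),
])
def test_contrastive_matches_bruteforce(n, temp, seed):
    rng = np.random.default_rng(seed)
    zs = rng.standard_normal((n, 6))
    zw = rng.standard_normal((n, 6))
    got = contrastive_loss(Tensor(zs), Tensor(zw), temperature=temp).item()
    want = ntxent_bruteforce(zs, zw, temp)
    assert got == pytest.approx(want, abs=1e-8)


def test_contrastive_identical_embeddings_equals_log_candidates():
    N = 4
    z = np.ones((N, 8))
    got = contrastive_loss(Tensor(z), Tensor(z.copy()), temperature=1.0).item()
    assert got == pytest.approx(math.log(2 * N - 1), abs=1e-8)


def test_contrastive_saturates_to_zero_with_aligned_positives():
    """Identical positives, orthogonal negatives, low temperature."""
    zs = np.eye(4)
    got = contrastive_loss(Tensor(zs), Tensor(zs.copy()),
                           temperature=0.01).item()
    assert got < 1e-6


def test_contrastive_invariant_to_common_permutation():
    rng = np.random.default_rng(9)
    zs = rng.standard_normal((6, 5))
    zw = rng.standard_normal((6, 5))
    perm = rng.permutation(6)
    a = contrastive_loss(Tensor(zs), Tensor(zw)).item()
    b = contrastive_loss(Tensor(zs[perm]), Tensor(zw[perm])).item()
    assert a == pytest.approx(b, abs=1e-10)


def test_contrastive_batch_of_one_rejected():
    z = np.ones((1, 4))
    with pytest.raises(ValueError, match="batch size"):
        contrastive_loss(Tensor(z), Tensor(z))


def test_contrastive_gradient_step_decreases_loss():
    """One Adam step on a learnable linear map lowers NT-Xent on a fixed
    tiny batch."""
    rng = np.random.default_rng(0)
    x_s = rng.standard_normal((4, 6))
    x_w = rng.standard_normal((4, 6))
    lin = Linear(6, 6, np.random.default_rng(1))
    opt = Adam(lin.parameters(), lr=1e-2)

    def compute():
        return contrastive_loss(lin(Tensor(x_s)), lin(Tensor(x_w)))

    before = compute()
    before.backward()
    opt.step()
    after = compute()
    assert after.item() < before.item()


def test_loss_weight_validation():
    with pytest.raises(ValueError):
        LossWeights(gamma=-0.1)
    with pytest.raises(ValueError):
        LossWeights(temperature_cl=0.0)
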