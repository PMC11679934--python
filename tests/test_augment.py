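"""Augmentation contracts: identities, parameter ranges, mask structure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tsrefine.augment import (AugmentationConfig, apply_mask,
                              build_view_batch, jitter, permute, sample_mask,
                              scale, strong_augment, weak_augment)


def test_defaults_match_protocol():
    cfg = AugmentationConfig()
    assert cfg.p_apply == 0.5
    assert cfg.scale_range == (0.5, 1.5)
    assert cfg.jitter_sigma_range == (0.0, 0.8)
    assert cfg.n_permute_segments == 5
    assert cfg.mask_ratio == 0.25


# ------------------------------------------------------------------ jitter

def test_jitter_sigma_zero_is_identity_and_shape_preserved():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((9, 128))
    out = jitter(x, 0.0, rng)
    np.testing.assert_array_equal(out, x)
    assert jitter(x, 0.5, rng).shape == (9, 128)


def test_jitter_noise_scale_matches_sigma():
    """Sample SD of the added noise within 3 SE of sigma over >= 1e4 points."""
    rng = np.random.default_rng(42)
    x = np.zeros((1, 20000))
    out = jitter(x, 0.5, rng)
    sd = out.std()
    se = 0.5 / np.sqrt(2 * 20000)   # SE of a Gaussian SD estimate
    assert abs(sd - 0.5) < 3 * se
    assert abs(out.mean()) < 3 * 0.5 / np.sqrt(20000)


def test_jitter_negative_sigma_rejected():
    with pytest.raises(ValueError, match="sigma"):
        jitter(np.zeros((1, 4)), -0.1, np.random.default_rng(0))


# ------------------------------------------------------------------- scale

def test_scale_identity_and_arithmetic():
    x = np.full((2, 8), 2.0)
    np.testing.assert_array_equal(scale(x, 1.0), x)
    np.testing.assert_array_equal(scale(x, 0.5), np.ones((2, 8)))


def test_drawn_scale_factors_stay_in_configured_range():
    cfg = AugmentationConfig(p_apply=1.0)
    rng = np.random.default_rng(0)
    draws = [rng.uniform(*cfg.scale_range) for _ in range(10_000)]
    assert min(draws) >= 0.5 and max(draws) <= 1.5


# ----------------------------------------------------------------- permute

def test_permute_single_segment_is_identity():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((2, 50))
    np.testing.assert_array_equal(permute(x, 1, rng), x)


def test_permute_preserves_per_channel_multiset():
    rng = np.random.default_rng(3)
    x = rng.standard_normal((3, 101))
    out = permute(x, 5, rng)
    for c in range(3):
        np.testing.assert_allclose(np.sort(out[c]), np.sort(x[c]))


def test_permute_on_ramp_yields_recoverable_segments():
    """A strictly increasing ramp must come back as a concatenation of
    (here 5) increasing runs whose boundaries reconstruct the permutation."""
    rng = np.random.default_rng(11)
    x = np.arange(100.0).reshape(1, 100)
    out = permute(x, 5, rng)[0]
    # segment boundaries = points where the ramp value drops or jumps != +1
    breaks = np.flatnonzero(np.diff(out) != 1.0)
    runs = np.split(out, breaks + 1)
    assert len(runs) <= 5
    for run in runs:
        assert np.all(np.diff(run) == 1.0) or run.size == 1
    # the recovered segments reassemble the original ramp exactly
    np.testing.assert_array_equal(
        np.concatenate(sorted(runs, key=lambda r: r[0])), x[0])


def test_permute_too_many_segments_rejected():
    with pytest.raises(ValueError, match="n_segments"):
        permute(np.zeros((1, 4)), 5, np.random.default_rng(0))


# ------------------------------------------------------- strong/weak views

def test_p_apply_zero_is_identity_for_both_strengths():
    cfg = AugmentationConfig(p_apply=0.0)
    rng = np.random.default_rng(0)
    x = np.random.default_rng(1).standard_normal((2, 64))
    np.testing.assert_array_equal(strong_augment(x, cfg, rng), x)
    np.testing.assert_array_equal(weak_augment(x, cfg, rng), x)


def test_p_apply_one_strong_changes_signal():
    cfg = AugmentationConfig(p_apply=1.0)
    rng = np.random.default_rng(0)
    x = np.random.default_rng(1).standard_normal((2, 64))
    out = strong_augment(x, cfg, rng)
    assert not np.array_equal(out, x)


@pytest.mark.parametrize("label,cfg", [
    # isolate one sub-augmentation at a time: the others are configured to
    # be exact identities, so output != input detects exactly one firing
    ("permute", AugmentationConfig(p_apply=0.5, n_permute_segments=5,
                                   jitter_sigma_range=(0.0, 0.0),
                                   scale_range=(1.0, 1.0))),
    ("jitter", AugmentationConfig(p_apply=0.5, n_permute_segments=1,
                                  jitter_sigma_range=(0.5, 0.5),
                                  scale_range=(1.0, 1.0))),
    ("scale", AugmentationConfig(p_apply=0.5, n_permute_segments=1,
                                 jitter_sigma_range=(0.0, 0.0),
                                 scale_range=(1.3, 1.5))),
])
def test_augmentation_application_frequency_is_binomial(label, cfg):
    """Each strong sub-augmentation fires at rate p_apply = 0.5 (3 sigma)."""
    rng = np.random.default_rng(123)
    n = 10_000
    x = np.random.default_rng(7).standard_normal((1, 64))
    fired = sum(not np.array_equal(strong_augment(x, cfg, rng), x)
                for _ in range(n))
    assert abs(fired / n - 0.5) < 3 * np.sqrt(0.25 / n)


def test_strong_weak_reproducible_from_rng_state():
    cfg = AugmentationConfig()
    x = np.random.default_rng(5).standard_normal((1, 128))
    a = strong_augment(x, cfg, np.random.default_rng(77))
    b = strong_augment(x, cfg, np.random.default_rng(77))
    np.testing.assert_array_equal(a, b)


# ----------------------------------------------------------------- masking

def test_mask_count_is_exact_for_stated_ratio():
    cfg = AugmentationConfig(mask_ratio=0.25)
    spec = sample_mask(3000, cfg, np.random.default_rng(0))
    assert spec.n_masked == 750


def test_mask_ratio_zero_masks_nothing():
    cfg = AugmentationConfig(mask_ratio=0.0)
    spec = sample_mask(100, cfg, np.random.default_rng(0))
    assert spec.n_masked == 0
    assert spec.keep_flags.all()


def test_mask_blocks_form_expected_runs():
    cfg = AugmentationConfig(mask_ratio=0.3, n_mask_blocks=3)
    spec = sample_mask(100, cfg, np.random.default_rng(1))
    assert spec.n_masked == 30
    assert spec.n_runs == 3


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    T=st.integers(min_value=10, max_value=600),
    ratio=st.floats(min_value=0.0, max_value=0.9),
    blocks=st.integers(min_value=1, max_value=6),
    seed=st.integers(min_value=0, max_value=2 ** 16),
)
def test_mask_invariants_hold_across_random_sweep(T, ratio, blocks, seed):
    """Exact count and contiguous-run structure for arbitrary (ratio, B, T)."""
    cfg = AugmentationConfig(mask_ratio=ratio, n_mask_blocks=blocks)
    spec = sample_mask(T, cfg, np.random.default_rng(seed))
    expected = int(round(ratio * T))
    assert spec.n_masked == expected
    if expected:
        assert 1 <= spec.n_runs <= blocks
        # runs can only be fewer than requested when separation or length
        # constraints force it
        if expected >= blocks and expected + blocks - 1 <= T:
            lengths_ok = expected - (-(-expected // blocks)) * (blocks - 1) >= 1
            if lengths_ok:
                assert spec.n_runs == blocks


def test_custom_position_sampler_hook():
    cfg = AugmentationConfig(mask_ratio=0.5)

    def head_masker(T, cfg, rng):
        keep = np.ones(T, dtype=bool)
        keep[:T // 2] = False
        return keep

    spec = sample_mask(10, cfg, np.random.default_rng(0),
                       position_sampler=head_masker)
    assert spec.n_masked == 5 and not spec.keep_flags[:5].any()


def test_apply_mask_identity_and_fill():
    x = np.ones((2, 10))
    cfg0 = AugmentationConfig(mask_ratio=0.0)
    spec0 = sample_mask(10, cfg0, np.random.default_rng(0))
    np.testing.assert_array_equal(apply_mask(x, spec0), x)
    cfg = AugmentationConfig(mask_ratio=0.5, n_mask_blocks=1)
    spec = sample_mask(10, cfg, np.random.default_rng(0))
    out = apply_mask(x, spec, fill=0.0)
    assert out.sum() == pytest.approx(x.sum() / 2)
    np.testing.assert_array_equal(out[:, spec.keep_flags],
                                  x[:, spec.keep_flags])


def test_apply_mask_length_mismatch_rejected():
    cfg = AugmentationConfig(mask_ratio=0.2)
    spec = sample_mask(8, cfg, np.random.default_rng(0))
    with pytest.raises(ValueError, match="length"):
        apply_mask(np.zeros((1, 9)), spec)


# -------------------------------------------------------------- view batch

def test_view_batch_cardinality_and_candidate_accounting():
    """N=4, K=1: four views per kind and 2N(K+1) = 16 contrastive signals."""
    rng = np.random.default_rng(0)
    x = np.random.default_rng(1).standard_normal((4, 1, 64))
    vb = build_view_batch(x, AugmentationConfig(n_masked_versions=1), rng)
    assert vb.strong_views.shape == (4, 1, 64)
    assert vb.weak_views.shape == (4, 1, 64)
    assert vb.masked_views.shape == (4, 1, 64)
    assert vb.n_contrastive_signals == 16
    vb2 = build_view_batch(x, AugmentationConfig(n_masked_versions=2), rng)
    assert vb2.n_contrastive_signals == 2 * 4 * 3


def test_view_batch_masked_views_match_augmented_base_off_mask():
    rng = np.random.default_rng(0)
    x = np.random.default_rng(2).standard_normal((3, 2, 50))
    vb = build_view_batch(x, AugmentationConfig(), rng)
    for i in range(3):
        keep = vb.mask_specs_strong[i][0].keep_flags
        np.testing.assert_array_equal(vb.masked_strong[i, 0][:, keep],
                                      vb.strong_views[i][:, keep])


def test_view_batch_identity_when_all_augmentation_off():
    rng = np.random.default_rng(0)
    x = np.random.default_rng(3).standard_normal((2, 1, 32))
    cfg = AugmentationConfig(p_apply=0.0, mask_ratio=0.0)
    vb = build_view_batch(x, cfg, rng)
    np.testing.assert_array_equal(vb.strong_views, x)
    np.testing.assert_array_equal(vb.weak_views, x)
    np.testing.assert_array_equal(vb.masked_strong[:, 0], x)


def test_view_batch_reproducible_and_validates_input():
    x = np.random.default_rng(4).standard_normal((3, 1, 40))
    cfg = AugmentationConfig()
    a = build_view_batch(x, cfg, np.random.default_rng(9))
    b = build_view_batch(x, cfg, np.random.default_rng(9))
    np.testing.assert_array_equal(a.strong_views, b.strong_views)
    np.testing.assert_array_equal(a.masked_strong, b.masked_strong)
    with pytest.raises(ValueError, match="non-empty"):
        build_view_batch(np.zeros((0, 1, 8)), cfg, np.random.default_rng(0))
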