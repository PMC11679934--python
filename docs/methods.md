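# Methods

## Model and training procedure

The package trains representations of fixed-length multi-channel time
series in three stages sharing one component chain.

**Tokenization.**  A window of shape (C, T) is cut into non-overlapping
patches of `patch_len` samples spanning all channels (right-edge
zero-padding when T is not a multiple), linearly projected to `d_model`,
and given learned positional embeddings.  Token count is ⌈T /
patch_len⌉ — e.g. 120 tokens for a 3000-sample window at `patch_len=25`.
Patch tokenization is our choice; it is standard for raw-signal
transformers and keeps attention cost quadratic in T/patch_len rather
than T.

**Encoder and aggregation.**  Three pre-norm transformer blocks
(width 128, 4 heads, feed-forward 256, dropout 0.1 under reference
settings).  The outputs of the last k = 3 blocks are collected and
concatenated channel-wise (384 channels), passed through multi-head
self-attention — scores softmax(QKᵀ/√d_head), weights applied to value
projections, rows summing to 1 — and reduced back to `d_agg` by two 1×1
convolutions.  Collecting-and-concatenating the per-layer features (rather
than summing them) preserves the depth-specific information the attention
can arbitrate over.

**Decoder.**  Two same-padding convolution blocks at width `decoder_dim`
followed by a two-layer MLP mapping each token back to patch space; the
patches are reassembled and cropped to T.  The exact depth is a design
choice (the architecture family, conv blocks + MLP, is fixed; depths are
configurable).

**Masking.**  Exactly round(mask_ratio · T) positions are masked, arranged
in `n_mask_blocks` contiguous runs (default 3; the last run may be
shorter) with uniformly random non-overlapping placement (stars-and-bars
over the free space, at least one kept sample between runs).  Block
masking — rather than i.i.d. dropout — forces reconstruction from context
instead of interpolation of isolated points.  Masked positions are filled
with 0, the per-channel mean of z-scored signals.  Masking is applied to
the time-augmented signal, so the augmented set shares a common base.
Mask *positions* are random at the default 0.25 ratio; `sample_mask`
accepts a pluggable position sampler as the hook for learned placement
policies.

**Losses.**  Reconstruction is the squared L2 distance between the
time-augmented (unmasked) signal and the reconstruction from its masked
variant.  The pairwise term treats a window and its masked variants as
positives and other windows' variants as negatives: with cosine-similarity
logits at temperature `temperature_pair` (default 0.2), it is the KL
divergence KL(p ‖ q) between the anchor's positive-restricted softmax p
and its full-candidate softmax q, averaged over anchors.  Minimizing this
KL aligns masked and unmasked representations; a sign convention that
*maximized* the divergence would contradict the stated goal of closely
aligned pairs, so the minimized form is used.  The total pre-training loss
is L_re + γ·L_pair with γ = 0.1 by default; an optional `auto_balance`
mode rescales the pairwise term to the reconstruction term's current
magnitude.  The refinement stage uses NT-Xent between strong- and
weak-view embeddings: each anchor's matched view is the positive, all
other embeddings from both views are negatives, cosine similarities are
divided by `temperature_cl` (default 0.2, the common convention for this
loss family).  All losses are means over anchors/samples so γ and learning
rates are batch-size independent.

Both contrastive-style losses are verified against independent
literal-loop evaluations of their defining sums (to 1e-8) in the test
suite, and every layer of the autodiff engine against central-difference
gradients.

**Stage contracts.**  Pre-training updates tokenizer, encoder, aggregation
and decoder; labels are never read (verified: permuting labels leaves the
checkpoint bit-identical).  Refinement trains only the pyramid and fusion
— backbone weights are excluded from the optimizer, its features are
detached, and a hash check asserts bit-identity before and after.
Fine-tuning defaults to a linear probe (dense head only; backbone and
refinement hashes verified unchanged), with `finetune_mode: full` as the
alternative.  Fine-tuning inputs receive the weak augmentation by default
(`finetune_augment`); evaluation always runs on clean signals in
evaluation mode, which is deterministic and bit-stable.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `augment.p_apply` | 0.5 | probability each augmentation fires |
| `augment.scale_range` | (0.5, 1.5) | multiplicative amplitude range |
| `augment.jitter_sigma_range` | (0, 0.8) | additive noise SD range (signal units; signals are z-scored) |
| `augment.n_permute_segments` | 5 | segments cut and reordered |
| `augment.mask_ratio` | 0.25 | fraction of timesteps masked |
| `augment.n_mask_blocks` | 3 | contiguous masked runs |
| `augment.n_masked_versions` | 1 | K masked variants per view |
| `encoder.d_model / n_blocks` | 128 / 3 | transformer width and depth |
| `encoder.pyramid_dims` | (256, 128, 64) | pyramid channel widths |
| `encoder.latent_dim` | 64 | contrastive embedding channels |
| `losses.gamma` | 0.1 | pairwise weight in pre-training |
| `losses.temperature_pair / _cl` | 0.2 / 0.2 | similarity temperatures |
| `stages.batch_size` | 128 | windows per optimizer step |
| `stages.lr_*` | 1e-3 / 1e-3 / 1e-4 | Adam learning rates per stage |

The weak augmentation ("scale-jitter") uses scale ∈ [0.9, 1.1] composed
with jitter sigma ≤ 0.1 — an order of magnitude gentler than the strong
view; no quantitative convention exists for "weak", so these are the
package's choice.  A circular time-shift augmentation is implemented but
disabled by default (`enable_shift`).  Optimizers are Adam without
schedulers; early stopping is off by default with a patience option.
With N originals and K masked variants per view, one batch exposes
2N(K+1) distinct signals to the contrastive machinery.

## Synthetic data: what it emulates and what it does not

`tsrefine.synth` generates class-conditional windows as sums of
class-specific sinusoids (random phase, ±20 % amplitude jitter, staggered
across channels) plus AR(1) noise (φ = 0.7) and optional Gaussian-windowed
oscillatory bursts, z-scored per channel.  This mimics the band-limited
oscillatory structure of EEG and the periodicity of inertial signals, and
has an analyzable spectrum: with noise off, the DFT magnitude argmax of a
window sits on its class frequency (tested).  Presets mirror common
benchmark geometries: 1 × 3000 samples at 100 Hz with 5 classes
(sleep-staging-like), 9 × 128 at 50 Hz with 6 classes (inertial-like).
Sampling rate is metadata; all computation is in samples.

The generator does **not** emulate non-stationary stage transitions,
1/f background spectra, artifacts, inter-subject variability, or
channel cross-correlation structure.  Passing tests therefore show the
pipeline's machinery is correct and that it recovers *spectral* class
structure from unlabeled data; they do not certify performance on real
polysomnography or inertial recordings.

**Recovery benchmark.**  `make_recovery_benchmark` fixes the conditions
used by the acceptance checks: 300 single-channel windows of 512 samples,
three classes with two tones each (3/8, 10/16, 20/26 Hz at 100 Hz), AR(1)
noise of SD 1.0 (the same order as a single tone's amplitude — random
phases and this noise level keep raw windows from separating linearly),
burst rate 0.5.  On a 70/30 split the pretrained-and-refined probe reaches
95–100 % held-out accuracy while an untrained encoder's probe stays near
chance (~25–35 %).

**Saturation caveat.**  The benchmark is easy enough that pre-training
*without* masking (plain autoencoding of the augmented signal) also
reaches the high 90s; the masking-ratio comparison is therefore a
non-inferiority check here (0.25 must not be worse than 0), not a
reproduction of the benefit masking shows on real, harder data.  At some
seeds the no-mask run edges ahead by 1–3 points — headroom, not masking,
is the binding constraint on this generator.

## Numerical and implementation choices

* Float64 throughout; softmax/log-softmax subtract a detached max.
* Zero-norm embeddings make cosine similarity undefined and raise rather
  than being clamped.
* Undefined metrics (empty confusion row/column) are reported as NaN/None,
  never silently 0; display rounds percentages to one decimal with
  round-half-even, comparisons in tests use |computed − printed| ≤ 0.05.
* The confusion-matrix convention is rows = actual, columns = predicted.
* Checkpoints store weights by dotted module path with an embedded JSON
  header (geometry + config); loading rebuilds the model exactly
  (bit-identical forward outputs, tested).
* One master seed per stage: model initialization and the data-order and
  augmentation streams are independent spawned substreams, so runs are
  bit-reproducible on a fixed platform.
* `desk_scale_config` (width 32, pyramid 64/32/16, 16-channel latent,
  batch 16–32) is the problem size used by the test suite and acceptance
  script; it keeps a full three-stage run around 20 s on one CPU while
  preserving the reference structure (3 blocks, k = 3, decreasing pyramid,
  linear probe).

## Known limitations

* The numpy autodiff engine is single-threaded and eager; it is sized for
  desk-scale experiments, not GPU-scale corpora.
* "Learnable masking" is realized as learned *reconstruction* of randomly
  placed masks; mask positions themselves are not optimized (the position-
  sampler hook exists for that extension).
* Multi-channel windows are mixed in the patch projection; no per-channel
  attention is provided.
* No EDF/EDF+ readers: real recordings must be windowed upstream and
  saved as the array-bundle format.
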