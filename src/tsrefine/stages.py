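"""Three-stage training orchestration.

* **Pre-training** (`run_pretrain`) — label-free.  Each batch is expanded
  into strong/weak augmented views with K masked variants; the tokenizer,
  encoder, aggregation and decoder are trained end-to-end to reconstruct the
  augmented signal from its masked version, plus the pairwise KL constraint
  pulling masked embeddings toward their sources.
* **Refinement** (`run_refine`) — the pre-trained backbone is frozen
  (aggregated features are detached; its weights are excluded from the
  optimizer, and the checkpoint hash is verified unchanged).  The pyramid
  and fusion layers are trained with the NT-Xent contrastive loss between
  strong-view and weak-view embeddings.
* **Fine-tuning** (`run_finetune`) — a dense head is trained with
  cross-entropy.  Default is a linear probe (head only, backbone and
  refinement untouched); ``finetune_mode="full"`` updates everything.

Every stage consumes a master seed, spawns independent substreams for data
order and augmentation, logs per-epoch losses, and emits a checkpoint that
round-trips bit-exactly.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np

from .augment import build_view_batch, weak_augment
from .config import RunConfig
from .data import DatasetBundle
from .io import Checkpoint, build_model_from_checkpoint, hash_state
from .losses import contrastive_loss, pretrain_loss
from .models import AggregatedFeature, ModelBundle
from .nn import Adam, Tensor

__all__ = ["StageResult", "run_pretrain", "run_refine", "run_finetune",
           "export_embeddings", "predict", "evaluate_model"]


@dataclass
class StageResult:
    stage_name: str
    loss_trace: list[float]
    checkpoint: Checkpoint
    rng_seed: int
    config_snapshot: dict
    extra: dict = field(default_factory=dict)


def _log(msg: str, verbose: bool) -> None:
    if verbose:
        print(msg, file=sys.stderr)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _pooled_embedding(model: ModelBundle, x: np.ndarray) -> Tensor:
    """Mean-pooled aggregated feature: the pre-training embedding."""
    agg = model.aggregate(Tensor(x))
    return agg.features.mean(axis=1)


def run_pretrain(dataset: DatasetBundle, config: RunConfig,
                 seed: int | None = None, verbose: bool = False) -> StageResult:
    """Stage 1: masked-reconstruction pre-training.  Labels are never read."""
    if len(dataset) == 0:
        raise ValueError("pre-training requires a non-empty dataset")
    seed = config.seed if seed is None else seed
    root = np.random.default_rng(seed)
    model_seed = int(root.integers(2 ** 31))
    data_rng, aug_rng = root.spawn(2)
    model = ModelBundle(dataset.n_channels, dataset.n_timesteps,
                        config.encoder, seed=model_seed)
    train_params = [p for m in (*model.backbone_modules().values(),
                                model.decoder)
                    for p in m.parameters()]
    opt = Adam(train_params, lr=config.stages.lr_pretrain)
    trace: list[float] = []
    for epoch in range(config.stages.epochs_pretrain):
        losses = []
        for idx in _batches(len(dataset), config.stages.batch_size, data_rng):
            if idx.size < 2:
                continue  # pairwise/contrastive terms need >= 2 samples
            vb = build_view_batch(dataset.signals[idx], config.augment, aug_rng)
            N, K, C, T = vb.masked_strong.shape
            masked_flat = vb.masked_strong.reshape(N * K, C, T)
            # reconstruct the augmented (unmasked) signal from its masked form
            agg_masked = model.aggregate(Tensor(masked_flat))
            xhat = model.decoder(agg_masked)
            target = np.repeat(vb.strong_views, K, axis=0)
            emb_masked = agg_masked.features.mean(axis=1)
            emb_orig = _pooled_embedding(model, vb.strong_views)
            from .nn import concatenate
            embeddings = concatenate([emb_orig, emb_masked], axis=0)
            pair_index = np.concatenate([np.arange(N), np.repeat(np.arange(N), K)])
            loss, parts = pretrain_loss(target, xhat, embeddings, pair_index,
                                        config.losses)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        trace.append(float(np.mean(losses)))
        _log(f"[pretrain] epoch {epoch + 1}/{config.stages.epochs_pretrain} "
             f"loss {trace[-1]:.4f}", verbose)
    ckpt = Checkpoint(model.state_dict(), config.encoder, dataset.n_channels,
                      dataset.n_timesteps, stage="pretrain",
                      run_config=config.to_dict())
    return StageResult("pretrain", trace, ckpt, seed, config.to_dict())


def run_refine(dataset: DatasetBundle, pretrain_ckpt: Checkpoint,
               config: RunConfig, seed: int | None = None,
               verbose: bool = False) -> StageResult:
    """Stage 2: contrastive refinement with a frozen backbone."""
    if len(dataset) < 2:
        raise ValueError("refinement requires at least two samples")
    seed = config.seed if seed is None else seed
    root = np.random.default_rng(seed)
    model_seed = int(root.integers(2 ** 31))
    data_rng, aug_rng = root.spawn(2)
    model = build_model_from_checkpoint(pretrain_ckpt, seed=model_seed)
    backbone_names = tuple(f"{name}." for name in model.backbone_modules())
    hash_before = hash_state({k: v for k, v in model.state_dict().items()
                              if k.startswith(backbone_names)})
    for m in model.backbone_modules().values():
        m.eval()  # freeze stochastic layers too
    refine_params = [p for m in model.refinement_modules().values()
                     for p in m.parameters()]
    opt = Adam(refine_params, lr=config.stages.lr_refine)
    trace: list[float] = []
    for epoch in range(config.stages.epochs_refine):
        losses = []
        for idx in _batches(len(dataset), config.stages.batch_size, data_rng):
            if idx.size < 2:
                continue
            vb = build_view_batch(dataset.signals[idx], config.augment, aug_rng)
            z_strong = model.embed(Tensor(vb.strong_views), detach_backbone=True)
            z_weak = model.embed(Tensor(vb.weak_views), detach_backbone=True)
            loss = contrastive_loss(z_strong, z_weak,
                                    config.losses.temperature_cl)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        trace.append(float(np.mean(losses)))
        _log(f"[refine] epoch {epoch + 1}/{config.stages.epochs_refine} "
             f"loss {trace[-1]:.4f}", verbose)
    state = model.state_dict()
    hash_after = hash_state({k: v for k, v in state.items()
                             if k.startswith(backbone_names)})
    if hash_before != hash_after:
        raise RuntimeError("backbone weights changed during refinement; "
                           "the freeze contract is violated")
    ckpt = Checkpoint(state, pretrain_ckpt.encoder_config,
                      dataset.n_channels, dataset.n_timesteps, stage="refine",
                      run_config=config.to_dict())
    return StageResult("refine", trace, ckpt, seed, config.to_dict(),
                       extra={"backbone_hash": hash_after})


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    logp = logits.log_softmax(axis=1)
    picked = logp[np.arange(labels.size), labels]
    return -picked.mean()


def run_finetune(dataset: DatasetBundle, refine_ckpt: Checkpoint,
                 config: RunConfig, seed: int | None = None,
                 verbose: bool = False) -> StageResult:
    """Stage 3: supervised fine-tuning of the dense head.

    ``finetune_mode='probe'`` (default) trains only the dense layer on
    detached embeddings; ``'full'`` updates the whole chain.
    """
    if dataset.labels is None:
        raise ValueError("fine-tuning requires a labeled dataset")
    n_classes = config.encoder.n_classes
    if dataset.labels.min() < 0 or dataset.labels.max() >= n_classes:
        raise ValueError(f"labels outside [0, {n_classes}); "
                         "adjust encoder.n_classes")
    seed = config.seed if seed is None else seed
    root = np.random.default_rng(seed)
    model_seed = int(root.integers(2 ** 31))
    data_rng, aug_rng = root.spawn(2)
    model = build_model_from_checkpoint(refine_ckpt, seed=model_seed)
    probe = config.stages.finetune_mode == "probe"
    if probe:
        model.eval()
        params = list(model.classifier.parameters())
        frozen_names = tuple(f"{n}." for n in (*model.backbone_modules(),
                                               *model.refinement_modules()))
        hash_before = hash_state({k: v for k, v in model.state_dict().items()
                                  if k.startswith(frozen_names)})
    else:
        params = list(model.parameters())
        frozen_names = ()
        hash_before = None
    opt = Adam(params, lr=config.stages.lr_finetune)
    trace: list[float] = []
    best = np.inf
    stall = 0
    # static embeddings: probe mode without augmentation lets us run the
    # backbone once and train the head on cached features
    static_emb = None
    if probe and not config.stages.finetune_augment:
        static_emb = np.concatenate(_eval_batches(
            model, dataset.signals, config.stages.batch_size,
            lambda m, x: m.embed(Tensor(x)).data))
    for epoch in range(config.stages.epochs_finetune):
        losses = []
        for idx in _batches(len(dataset), config.stages.batch_size, data_rng):
            y = dataset.labels[idx]
            if static_emb is not None:
                z = Tensor(static_emb[idx])
            else:
                x = dataset.signals[idx]
                if config.stages.finetune_augment:
                    x = np.stack([weak_augment(w, config.augment, aug_rng)
                                  for w in x])
                z = model.embed(Tensor(x), detach_backbone=probe)
                if probe:
                    z = z.detach()
            loss = _cross_entropy(model.classifier(z), y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        trace.append(float(np.mean(losses)))
        _log(f"[finetune] epoch {epoch + 1}/{config.stages.epochs_finetune} "
             f"loss {trace[-1]:.4f}", verbose)
        patience = config.stages.early_stop_patience
        if patience:
            if trace[-1] < best - 1e-6:
                best, stall = trace[-1], 0
            else:
                stall += 1
                if stall >= patience:
                    _log(f"[finetune] early stop at epoch {epoch + 1}", verbose)
                    break
    state = model.state_dict()
    if probe:
        hash_after = hash_state({k: v for k, v in state.items()
                                 if k.startswith(frozen_names)})
        if hash_before != hash_after:
            raise RuntimeError("backbone changed in linear-probe mode")
    ckpt = Checkpoint(state, refine_ckpt.encoder_config, dataset.n_channels,
                      dataset.n_timesteps, stage="finetune",
                      run_config=config.to_dict())
    return StageResult("finetune", trace, ckpt, seed, config.to_dict())


def _eval_batches(model: ModelBundle, signals: np.ndarray, batch_size: int,
                  fn) -> list[np.ndarray]:
    out = []
    for start in range(0, signals.shape[0], batch_size):
        out.append(fn(model, signals[start:start + batch_size]))
    return out


def predict(dataset: DatasetBundle, ckpt: Checkpoint,
            batch_size: int = 128) -> np.ndarray:
    """Class predictions (argmax of the dense-head scores); deterministic."""
    model = build_model_from_checkpoint(ckpt)
    model.eval()
    logits = _eval_batches(
        model, dataset.signals, batch_size,
        lambda m, x: m.logits(Tensor(x)).data)
    return np.concatenate(logits).argmax(axis=1)


def evaluate_model(dataset: DatasetBundle, ckpt: Checkpoint,
                   batch_size: int = 128):
    """Confusion matrix + metrics of a fine-tuned checkpoint on a dataset."""
    from .metrics import confusion_matrix, per_class_metrics
    if dataset.labels is None:
        raise ValueError("evaluation requires labels")
    y_pred = predict(dataset, ckpt, batch_size)
    n_classes = ckpt.encoder_config.n_classes
    names = dataset.metadata.get("class_names") or []
    cm = confusion_matrix(dataset.labels, y_pred, n_classes,
                          list(names)[:n_classes] if len(names) == n_classes
                          else None)
    return per_class_metrics(cm)


def export_embeddings(dataset: DatasetBundle, ckpt: Checkpoint,
                      batch_size: int = 128):
    """One latent embedding per sample, as a DataFrame
    (sample_id, label, e0..e{D-1}); deterministic given the checkpoint."""
    import pandas as pd
    model = build_model_from_checkpoint(ckpt)
    model.eval()
    embs = np.concatenate(_eval_batches(
        model, dataset.signals, batch_size,
        lambda m, x: m.embed(Tensor(x)).data))
    frame = pd.DataFrame(embs, columns=[f"e{i}" for i in range(embs.shape[1])])
    frame.insert(0, "label", dataset.labels if dataset.labels is not None
                 else -1)
    frame.insert(0, "sample_id", np.arange(len(dataset)))
    return frame
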