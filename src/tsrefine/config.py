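"""Run configuration: nested sections, schema-validated, YAML round-trip.

A :class:`RunConfig` bundles one section per component — augmentation,
encoder architecture, loss weights, stage schedule — plus the master seed
and output directory.  Unknown keys are rejected so typos fail loudly;
omitted sections and keys fall back to the documented defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .augment import AugmentationConfig
from .losses import LossWeights
from .models import EncoderConfig

__all__ = ["StageConfig", "RunConfig", "desk_scale_config"]


@dataclass
class StageConfig:
    """Training schedule for the three stages.

    ``finetune_mode`` is ``"probe"`` (train the dense head only; default) or
    ``"full"`` (update every component).  ``finetune_augment`` applies the
    weak augmentation to fine-tuning inputs; evaluation always runs on
    un-augmented signals.  ``early_stop_patience`` of ``0`` disables early
    stopping (the default).
    """

    epochs_pretrain: int = 10
    epochs_refine: int = 10
    epochs_finetune: int = 20
    batch_size: int = 128
    lr_pretrain: float = 1e-3
    lr_refine: float = 1e-3
    lr_finetune: float = 1e-4
    finetune_mode: str = "probe"
    finetune_augment: bool = True
    early_stop_patience: int = 0

    def __post_init__(self) -> None:
        if self.finetune_mode not in ("probe", "full"):
            raise ValueError(f"finetune_mode must be 'probe' or 'full', "
                             f"got {self.finetune_mode!r}")
        for name in ("epochs_pretrain", "epochs_refine", "epochs_finetune",
                     "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


def _section_from_dict(cls, payload: dict, section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(payload) - allowed
    if unknown:
        raise ValueError(f"unknown keys in section {section!r}: "
                         f"{sorted(unknown)}")
    coerced = {}
    for f in fields(cls):
        if f.name in payload:
            value = payload[f.name]
            if isinstance(value, list):
                value = tuple(value)
            coerced[f.name] = value
    return cls(**coerced)


@dataclass
class RunConfig:
    augment: AugmentationConfig = field(default_factory=AugmentationConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    losses: LossWeights = field(default_factory=LossWeights)
    stages: StageConfig = field(default_factory=StageConfig)
    seed: int = 0
    outdir: str = "runs"

    _SECTIONS = {"augment": AugmentationConfig, "encoder": EncoderConfig,
                 "losses": LossWeights, "stages": StageConfig}

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        unknown = set(payload) - set(cls._SECTIONS) - {"seed", "outdir"}
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in cls._SECTIONS.items():
            section = payload.get(name, {})
            if not isinstance(section, dict):
                raise ValueError(f"section {name!r} must be a mapping")
            kwargs[name] = _section_from_dict(section_cls, section, name)
        kwargs["seed"] = int(payload.get("seed", 0))
        kwargs["outdir"] = str(payload.get("outdir", "runs"))
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        out = {}
        for name in self._SECTIONS:
            section = dataclasses.asdict(getattr(self, name))
            out[name] = {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in section.items()}
        out["seed"] = self.seed
        out["outdir"] = self.outdir
        return out

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def apply_overrides(self, overrides: dict[str, object]) -> "RunConfig":
        """Return a copy with dotted-key overrides (``augment.mask_ratio``)
        applied; unknown keys raise."""
        payload = self.to_dict()
        for dotted, value in overrides.items():
            parts = dotted.split(".")
            node = payload
            for p in parts[:-1]:
                if p not in node:
                    raise ValueError(f"unknown config key {dotted!r}")
                node = node[p]
            if parts[-1] not in node:
                raise ValueError(f"unknown config key {dotted!r}")
            node[parts[-1]] = value
        return RunConfig.from_dict(payload)


def desk_scale_config(n_classes: int = 3, seed: int = 0) -> RunConfig:
    """Compact single-CPU configuration for the synthetic benchmarks.

    Narrower than the reference architecture (width 32 instead of 128,
    pyramid 64/32/16, 16-channel latent) and with a training schedule sized
    for a few hundred short windows; the structure — 3 encoder blocks, k=3
    extracted layers, strictly decreasing pyramid, linear probe — is
    unchanged.
    """
    return RunConfig.from_dict({
        "encoder": {"d_model": 32, "n_heads": 2, "ff_dim": 64,
                    "patch_len": 32, "d_agg": 32,
                    "pyramid_dims": [64, 32, 16], "latent_dim": 16,
                    "n_classes": n_classes, "dropout": 0.0,
                    "decoder_dim": 32},
        "stages": {"epochs_pretrain": 30, "epochs_refine": 15,
                   "epochs_finetune": 80, "batch_size": 32,
                   "lr_finetune": 1e-2, "finetune_augment": False},
        "seed": seed,
    })
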