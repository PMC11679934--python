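"""Persistence: array-bundle datasets, model checkpoints, metrics files.

Datasets are stored as compressed ``.npz`` archives with named arrays
(``signals``, optionally ``labels``) plus a JSON sidecar
(``<stem>.meta.json``) carrying sampling rate, class names and provenance.
Checkpoints are ``.npz`` weight archives with an embedded JSON header
recording the architecture, geometry, stage provenance and package version,
so a checkpoint alone is sufficient to rebuild the model.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .data import DatasetBundle
from .models import EncoderConfig, ModelBundle

__all__ = ["save_dataset", "load_dataset", "Checkpoint", "save_checkpoint",
           "load_checkpoint", "hash_state", "build_model_from_checkpoint"]


# ------------------------------------------------------------------ datasets

def _sidecar(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".meta.json")


def save_dataset(bundle: DatasetBundle, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {"signals": bundle.signals}
    if bundle.labels is not None:
        arrays["labels"] = bundle.labels
    np.savez_compressed(path, **arrays)
    with open(_sidecar(path), "w") as fh:
        json.dump(bundle.metadata, fh, indent=2, default=str)


def load_dataset(path: str | Path) -> DatasetBundle:
    path = Path(path)
    with np.load(path) as archive:
        if "signals" not in archive:
            raise ValueError(f"{path} is not a dataset bundle: "
                             "missing 'signals' array")
        signals = archive["signals"]
        labels = archive["labels"] if "labels" in archive else None
    if not np.all(np.isfinite(signals)):
        raise ValueError(f"{path} contains non-finite signal values")
    metadata = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            metadata = json.load(fh)
    return DatasetBundle(signals, labels, metadata)


# ---------------------------------------------------------------- checkpoints

@dataclass
class Checkpoint:
    state: dict[str, np.ndarray]
    encoder_config: EncoderConfig
    n_channels: int
    n_timesteps: int
    stage: str
    run_config: dict | None = None
    version: str = __version__

    def weight_hash(self, prefix: str = "") -> str:
        sub = {k: v for k, v in self.state.items() if k.startswith(prefix)}
        return hash_state(sub)


def hash_state(state: dict[str, np.ndarray]) -> str:
    """Order-independent SHA-256 digest of a named weight collection."""
    h = hashlib.sha256()
    for name in sorted(state):
        h.update(name.encode())
        h.update(np.ascontiguousarray(state[name], dtype=np.float64).tobytes())
    return h.hexdigest()


def save_checkpoint(ckpt: Checkpoint, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "encoder_config": dataclasses.asdict(ckpt.encoder_config),
        "n_channels": ckpt.n_channels,
        "n_timesteps": ckpt.n_timesteps,
        "stage": ckpt.stage,
        "run_config": ckpt.run_config,
        "version": ckpt.version,
    }
    arrays = {f"param::{k}": v for k, v in ckpt.state.items()}
    arrays["__header__"] = np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path: str | Path) -> Checkpoint:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path) as archive:
        if "__header__" not in archive:
            raise ValueError(f"{path} is not a checkpoint archive")
        header = json.loads(bytes(archive["__header__"]).decode())
        state = {k[len("param::"):]: archive[k]
                 for k in archive.files if k.startswith("param::")}
    enc = header["encoder_config"]
    enc["pyramid_dims"] = tuple(enc["pyramid_dims"])
    return Checkpoint(
        state=state,
        encoder_config=EncoderConfig(**enc),
        n_channels=int(header["n_channels"]),
        n_timesteps=int(header["n_timesteps"]),
        stage=header["stage"],
        run_config=header.get("run_config"),
        version=header.get("version", "unknown"),
    )


def build_model_from_checkpoint(ckpt: Checkpoint, seed: int = 0) -> ModelBundle:
    model = ModelBundle(ckpt.n_channels, ckpt.n_timesteps,
                        ckpt.encoder_config, seed=seed)
    model.load_state_dict(ckpt.state)
    return model
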