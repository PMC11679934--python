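"""In-memory dataset container shared by every stage.

A :class:`DatasetBundle` holds windowed multi-channel time series as a single
``(n_samples, n_channels, n_timesteps)`` float array plus an optional integer
label vector and free-form metadata (sampling rate, class names, provenance).
Sampling rate is metadata only — all computation operates in samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DatasetBundle"]


@dataclass
class DatasetBundle:
    signals: np.ndarray                # (n_samples, n_channels, n_timesteps)
    labels: np.ndarray | None = None   # (n_samples,) int, optional
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 3:
            raise ValueError("signals must be (n_samples, n_channels, "
                             f"n_timesteps); got ndim={self.signals.ndim}")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals contain non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.signals.shape[0],):
                raise ValueError(
                    f"labels length {self.labels.shape} does not match "
                    f"n_samples {self.signals.shape[0]}")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]

    @property
    def n_timesteps(self) -> int:
        return self.signals.shape[2]

    def subset(self, idx) -> "DatasetBundle":
        labels = self.labels[idx] if self.labels is not None else None
        return DatasetBundle(self.signals[idx], labels, dict(self.metadata))

    def __len__(self) -> int:
        return self.n_samples
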