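"""Core epoch container shared by the synthetic generator and EDF I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EpochSet"]


@dataclass
class EpochSet:
    """A set of fixed-length multichannel epochs with binary class labels.

    ``data`` has shape (n_epochs, n_channels, n_samples); ``labels`` is a
    vector of 0 (seizure-free) / 1 (seizure) with one entry per epoch.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must match epoch count")
        if not self.channel_labels:
            self.channel_labels = [f"CH{c}" for c in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must match channel count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def class_counts(self) -> tuple[int, int]:
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))
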