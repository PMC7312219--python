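"""Per-sub-band energy and fractal-dimension features.

Four scalars are computed from every sub-band (IMF or wavelet band):

* instantaneous energy  — log10 of the mean squared amplitude,
* Teager energy         — log10 of the mean absolute Teager-Kaiser
                          operator output over interior samples,
* Higuchi fractal dimension,
* Petrosian fractal dimension.

With EMD decomposition (2 kept IMFs) this yields 8 features per channel;
with the 4-level DWT (5 sub-bands) it yields 20.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import decompose
from .epochs import EpochSet

__all__ = [
    "HiguchiConfig",
    "FeatureTable",
    "instantaneous_energy",
    "teager_energy",
    "higuchi_fd",
    "petrosian_fd",
    "band_features",
    "channel_features",
    "build_feature_table",
]

#: floor inside the log10 of both energy features, for silent bands
ENERGY_EPS = 1e-12

FEATURE_NAMES = ("ienergy", "teager", "higuchi", "petrosian")


@dataclass(frozen=True)
class HiguchiConfig:
    """Higuchi curve-length settings: maximum interval time ``k_max``."""

    k_max: int = 10

    def __post_init__(self) -> None:
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")


def instantaneous_energy(band: np.ndarray) -> float:
    """log10 of the mean squared amplitude of ``band``.

    Values below ``ENERGY_EPS`` are floored so silent bands map to -12.
    """
    band = np.asarray(band, dtype=float)
    if band.size < 1:
        raise ValueError("band must contain at least one sample")
    ms = np.mean(band**2)
    return float(np.log10(max(ms, ENERGY_EPS)))


def teager_energy(band: np.ndarray) -> float:
    """log10 of the mean absolute Teager-Kaiser energy of ``band``.

    The operator ``w(r)^2 - w(r-1) * w(r+1)`` is summed over the interior
    samples r = 2..N-1 (both neighbours must exist) and divided by N.
    """
    band = np.asarray(band, dtype=float)
    n = band.size
    if n < 3:
        raise ValueError("Teager energy needs at least 3 samples")
    op = band[1:-1] ** 2 - band[:-2] * band[2:]
    mean_abs = np.sum(np.abs(op)) / n
    return float(np.log10(max(mean_abs, ENERGY_EPS)))


def _higuchi_curve_lengths(x: np.ndarray, k: int) -> np.ndarray:
    """L_m(k) for m = 1..k: normalized mean absolute k-spaced increments."""
    n = x.size
    lengths = np.empty(k)
    for m in range(1, k + 1):
        n_seg = (n - m) // k  # number of increments for this offset
        if n_seg < 1:
            lengths[m - 1] = 0.0
            continue
        idx = m - 1 + np.arange(n_seg + 1) * k
        diffs = np.abs(np.diff(x[idx]))
        norm = (n - 1) / (n_seg * k)
        lengths[m - 1] = diffs.sum() * norm / k
    return lengths


def higuchi_fd(signal: np.ndarray, config: HiguchiConfig = HiguchiConfig()) -> float:
    """Higuchi fractal dimension of ``signal``.

    Slope magnitude of the least-squares fit of ln L(k) against
    ln(1/k) for k = 1..k_max, where L(k) is the mean curve length over
    the k offset subsequences.  Returns 0 (with a warning) for
    constant signals, whose curve length is identically zero.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if not 2 <= config.k_max < n / 2:
        raise ValueError(f"k_max={config.k_max} out of range for N={n}")
    ks = np.arange(1, config.k_max + 1)
    mean_lengths = np.array([_higuchi_curve_lengths(x, int(k)).mean() for k in ks])
    if np.any(mean_lengths <= 0):
        warnings.warn("degenerate (constant) signal: Higuchi FD set to 0", stacklevel=2)
        return 0.0
    slope, _ = np.polyfit(np.log(1.0 / ks), np.log(mean_lengths), 1)
    return float(abs(slope))


def petrosian_fd(signal: np.ndarray) -> float:
    """Petrosian fractal dimension of ``signal``.

    The series is binarized by the sign of its first difference (zeros
    inherit the previous sign); ``n_delta`` counts sign changes between
    consecutive differences.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Petrosian FD needs at least 3 samples")
    diffs = np.diff(x)
    signs = np.sign(diffs)
    # zeros inherit the previous nonzero sign (leading zeros stay 0)
    for i in range(1, signs.size):
        if signs[i] == 0:
            signs[i] = signs[i - 1]
    n_delta = int(np.sum(signs[1:] * signs[:-1] < 0))
    log_n = np.log10(n)
    return float(log_n / (log_n + np.log10(n / (n + 0.4 * n_delta))))


def band_features(band: np.ndarray, higuchi: HiguchiConfig = HiguchiConfig()) -> np.ndarray:
    """The four per-sub-band features, in fixed order."""
    band = np.asarray(band, dtype=float)
    if np.allclose(band, band[0] if band.size else 0.0):
        # degenerate band: energy floors, smooth-curve FD limits
        return np.array([instantaneous_energy(band) if band.size else np.log10(ENERGY_EPS),
                         np.log10(ENERGY_EPS) if band.size < 3 else teager_energy(band),
                         0.0,
                         1.0])
    k_max = higuchi.k_max
    if band.size <= 2 * k_max:  # short wavelet bands: shrink k_max
        k_max = max(2, band.size // 2 - 1)
    return np.array([
        instantaneous_energy(band),
        teager_energy(band),
        higuchi_fd(band, HiguchiConfig(k_max=k_max)),
        petrosian_fd(band),
    ])


def channel_features(
    channel_epoch: np.ndarray,
    method: str,
    emd_config: decompose.EmdConfig | None = None,
    higuchi: HiguchiConfig = HiguchiConfig(),
) -> np.ndarray:
    """Feature vector for one channel of one epoch.

    ``method='emd'`` -> ``n_keep`` selected IMFs x 4 features (8 at the
    default ``n_keep=2``); missing IMFs are zero-band placeholders so the
    vector length is fixed.  ``method='dwt'`` -> 5 sub-bands x 4 = 20.
    """
    x = np.asarray(channel_epoch, dtype=float)
    method = method.lower()
    if method == "emd":
        cfg = emd_config or decompose.EmdConfig()
        imfs, _residue = decompose.sift_emd(x, cfg)
        order = decompose.select_imfs(x, imfs, n_keep=cfg.n_keep, p=cfg.minkowski_p)
        bands = [imfs[i].samples for i in order]
        while len(bands) < cfg.n_keep:  # degenerate epochs: zero-fill
            bands.append(np.zeros(4))
    elif method == "dwt":
        bands = [sb.samples for sb in decompose.dwt_decompose(x)]
    else:
        raise ValueError(f"unknown method {method!r}; expected 'emd' or 'dwt'")
    return np.concatenate([band_features(b, higuchi) for b in bands])


@dataclass
class FeatureTable:
    """Instances x (channels x per-channel features) matrix with labels.

    ``block_index`` maps a channel index to its column ``slice``; blocks
    partition the columns in montage order.
    """

    matrix: np.ndarray
    labels: np.ndarray
    channel_labels: list[str]
    features_per_channel: int
    method: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        c = len(self.channel_labels)
        if self.matrix.shape[1] != c * self.features_per_channel:
            raise ValueError("column count must equal n_channels * features_per_channel")
        if self.matrix.shape[0] != self.labels.size:
            raise ValueError("one label per row required")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def block_index(self, channel: int) -> slice:
        f = self.features_per_channel
        if not 0 <= channel < self.n_channels:
            raise IndexError(f"channel {channel} out of range")
        return slice(channel * f, (channel + 1) * f)

    def subset_columns(self, channels) -> np.ndarray:
        """Column indices for a channel subset, in montage order."""
        cols: list[int] = []
        for ch in sorted(channels):
            cols.extend(range(*self.block_index(ch).indices(self.matrix.shape[1])))
        return np.array(cols, dtype=int)

    def column_names(self) -> list[str]:
        names = []
        if self.method == "emd":
            bands = [f"IMF{i + 1}" for i in range(self.features_per_channel // 4)]
        else:
            bands = ["A4", "D4", "D3", "D2", "D1"]
        for ch in self.channel_labels:
            for b in bands:
                for f in FEATURE_NAMES:
                    names.append(f"{ch}__{b}__{f}")
        return names

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.matrix, columns=self.column_names())
        df.insert(0, "label", self.labels)
        df.to_csv(path, index=False)  # default float repr round-trips exactly

    @classmethod
    def from_csv(cls, path, method: str) -> "FeatureTable":
        df = pd.read_csv(path, float_precision="round_trip")
        labels = df.pop("label").to_numpy()
        cols = list(df.columns)
        channel_labels: list[str] = []
        for c in cols:
            ch = c.split("__")[0]
            if not channel_labels or channel_labels[-1] != ch:
                channel_labels.append(ch)
        f = len(cols) // len(channel_labels)
        return cls(df.to_numpy(), labels, channel_labels, f, method)


def build_feature_table(
    epochs: EpochSet,
    method: str,
    emd_config: decompose.EmdConfig | None = None,
    higuchi: HiguchiConfig = HiguchiConfig(),
) -> FeatureTable:
    """Feature matrix for an epoch set: one row per epoch, channel blocks
    in montage order."""
    method = method.lower()
    if method == "emd":
        cfg = emd_config or decompose.EmdConfig()
        f = 4 * cfg.n_keep
    elif method == "dwt":
        f = 20
    else:
        raise ValueError(f"unknown method {method!r}")
    rows = np.empty((epochs.n_epochs, epochs.n_channels * f))
    for i in range(epochs.n_epochs):
        for ch in range(epochs.n_channels):
            rows[i, ch * f:(ch + 1) * f] = channel_features(
                epochs.data[i, ch], method, emd_config=emd_config, higuchi=higuchi
            )
    return FeatureTable(rows, epochs.labels, list(epochs.channel_labels), f, method)
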