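"""Sub-band decomposition: empirical mode decomposition and a 4-level
biorthogonal-2.2 discrete wavelet filter bank.

Both paths produce :class:`SubBand` objects carrying the coefficient
sequence, an origin tag (``IMF1`` ... or ``A4``/``D4``/``D3``/``D2``/``D1``)
and, for wavelet bands, the nominal frequency range.

The wavelet transform is implemented directly (cascaded half-band
analysis filters with symmetric half-sample extension and dyadic
decimation) because no wavelet library is assumed at runtime; the filter
taps are the standard spline-based biorthogonal 2.2 analysis pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import argrelextrema

__all__ = [
    "SubBand",
    "EmdConfig",
    "sift_emd",
    "select_imfs",
    "dwt_decompose",
    "DWT_BAND_TAGS",
    "dwt_nominal_bands",
]

# bior2.2 analysis filters (low/high-pass), spline construction:
# dec_lo = [0, -1, 2, 6, 2, -1] * sqrt(2)/8 ; dec_hi = [0, 1, -2, 1, 0, 0] * sqrt(2)/4
_SQ2 = np.sqrt(2.0)
DEC_LO = np.array([0.0, -1.0, 2.0, 6.0, 2.0, -1.0]) * _SQ2 / 8.0
DEC_HI = np.array([0.0, 1.0, -2.0, 1.0, 0.0, 0.0]) * _SQ2 / 4.0

DWT_BAND_TAGS = ("A4", "D4", "D3", "D2", "D1")


@dataclass
class SubBand:
    """One oscillatory component of one channel's epoch."""

    samples: np.ndarray
    origin: str
    nominal_band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def length(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class EmdConfig:
    """EMD sifting and IMF-selection parameters."""

    max_imfs: int = 10
    max_sift_iters: int = 50
    sd_threshold: float = 0.2
    spline: str = "cubic"
    n_keep: int = 2
    minkowski_p: float = 2.0

    def __post_init__(self) -> None:
        if self.n_keep < 1:
            raise ValueError("n_keep must be >= 1")
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be > 0")


# ---------------------------------------------------------------------------
# EMD


def _extrema_indices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    maxima = argrelextrema(x, np.greater_equal, order=1)[0]
    minima = argrelextrema(x, np.less_equal, order=1)[0]
    # drop plateaus duplicated by >= / <= comparators
    maxima = _dedupe_plateaus(maxima, x)
    minima = _dedupe_plateaus(minima, x)
    # interior extrema only
    maxima = maxima[(maxima > 0) & (maxima < x.size - 1)]
    minima = minima[(minima > 0) & (minima < x.size - 1)]
    return maxima, minima


def _dedupe_plateaus(idx: np.ndarray, x: np.ndarray) -> np.ndarray:
    if idx.size < 2:
        return idx
    keep = [idx[0]]
    for i in idx[1:]:
        if i != keep[-1] + 1 or x[i] != x[keep[-1]]:
            keep.append(i)
    return np.asarray(keep)


def _envelope(x: np.ndarray, extrema: np.ndarray, kind: str) -> np.ndarray:
    """Cubic-spline envelope through extrema with 2 mirrored boundary
    extrema at each end (reduces the classic end effect)."""
    n = x.size
    t = extrema.astype(float)
    v = x[extrema]
    n_mirror = min(2, extrema.size)
    left_t = 2 * 0 - t[1:n_mirror + 1][::-1] if extrema.size > 1 else np.array([-t[0] - 1])
    left_v = v[1:n_mirror + 1][::-1] if extrema.size > 1 else v[:1]
    right_t = 2 * (n - 1) - t[-n_mirror - 1:-1][::-1] if extrema.size > 1 else np.array([2 * (n - 1) - t[-1] + 1])
    right_v = v[-n_mirror - 1:-1][::-1] if extrema.size > 1 else v[-1:]
    tt = np.concatenate([left_t, t, right_t])
    vv = np.concatenate([left_v, v, right_v])
    # guard against non-monotonic knots after mirroring
    order = np.argsort(tt)
    tt, vv = tt[order], vv[order]
    keep = np.concatenate([[True], np.diff(tt) > 0])
    tt, vv = tt[keep], vv[keep]
    if tt.size < 2:
        return np.full(n, vv[0])
    if kind == "cubic" and tt.size >= 4:
        spline = CubicSpline(tt, vv)
        return spline(np.arange(n))
    return np.interp(np.arange(n), tt, vv)


def _count_zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    return int(np.sum(s[1:] != s[:-1]))


def sift_emd(signal: np.ndarray, config: EmdConfig = EmdConfig()) -> tuple[list[SubBand], np.ndarray]:
    """Decompose ``signal`` into IMFs by sifting; returns (imfs, residue).

    Sifting of one IMF stops when the normalized squared change between
    consecutive siftings drops below ``sd_threshold`` or after
    ``max_sift_iters`` iterations.  Extraction stops when the residue has
    fewer than 3 interior extrema or ``max_imfs`` is reached.  The sum of
    all IMFs plus the residue reconstructs the input exactly.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 8:
        raise ValueError("signal too short for sifting")
    residue = x.copy()
    imfs: list[SubBand] = []
    for k in range(config.max_imfs):
        maxima, minima = _extrema_indices(residue)
        if maxima.size < 2 or minima.size < 2:
            break
        h = residue.copy()
        for _ in range(config.max_sift_iters):
            maxima, minima = _extrema_indices(h)
            if maxima.size < 2 or minima.size < 2:
                break
            upper = _envelope(h, maxima, config.spline)
            lower = _envelope(h, minima, config.spline)
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            denom = np.sum(h**2)
            sd = np.sum((h - h_new) ** 2) / denom if denom > 0 else 0.0
            h = h_new
            if sd < config.sd_threshold:
                break
        imfs.append(SubBand(h, origin=f"IMF{k + 1}"))
        residue = residue - h
        maxima, minima = _extrema_indices(residue)
        if maxima.size + minima.size < 3:
            break
    return imfs, residue


def select_imfs(signal: np.ndarray, imfs: list[SubBand], n_keep: int = 2, p: float = 2.0) -> list[int]:
    """Indices of the ``n_keep`` IMFs closest to ``signal`` in l_p
    distance, ascending by distance (ties broken by lower IMF index).

    Distant IMFs are the redundant ones; the closest carry the dominant
    oscillatory content of the original signal.
    """
    x = np.asarray(signal, dtype=float)
    if not imfs:
        return []
    dists = [float(np.sum(np.abs(imf.samples - x) ** p) ** (1.0 / p)) for imf in imfs]
    order = sorted(range(len(imfs)), key=lambda i: (dists[i], i))
    return order[:n_keep]


# ---------------------------------------------------------------------------
# DWT


def _dwt_single(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One analysis level: symmetric extension, filter, dyadic decimation.

    Output length per band is floor((n + L - 1) / 2) with L = 6.
    """
    flen = DEC_LO.size
    # symmetric half-sample extension by L-1 on each side
    left = x[:flen - 1][::-1]
    right = x[-1:-flen:-1]
    ext = np.concatenate([left, x, right])
    approx = np.convolve(ext, DEC_LO, mode="valid")[1::2]
    detail = np.convolve(ext, DEC_HI, mode="valid")[1::2]
    return approx, detail


def dwt_nominal_bands(fs: float, levels: int) -> list[tuple[float, float]]:
    """Nominal Hz ranges for [A_J, D_J, ..., D_1] at sampling rate ``fs``."""
    ny = fs / 2.0
    bands = [(0.0, ny / 2**levels)]
    for lvl in range(levels, 0, -1):
        bands.append((ny / 2**lvl, ny / 2 ** (lvl - 1)))
    return bands


def dwt_decompose(signal: np.ndarray, levels: int = 4, fs: float = 128.0) -> list[SubBand]:
    """Cascaded bior2.2 analysis filter bank.

    Returns ``levels + 1`` sub-bands ordered [A_J, D_J, ..., D_1]; at the
    default 4 levels and fs = 128 the nominal bands are 0-4, 4-8, 8-16,
    16-32 and 32-64 Hz.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2**levels:
        raise ValueError(f"signal of length {x.size} too short for {levels} levels")
    details: list[np.ndarray] = []
    approx = x
    for _ in range(levels):
        approx, detail = _dwt_single(approx)
        details.append(detail)
    bands = dwt_nominal_bands(fs, levels)
    if levels == 4:
        tags = list(DWT_BAND_TAGS)
    else:
        tags = [f"A{levels}"] + [f"D{lvl}" for lvl in range(levels, 0, -1)]
    coeff_seqs = [approx] + details[::-1]
    return [
        SubBand(c, origin=t, nominal_band=b)
        for c, t, b in zip(coeff_seqs, tags, bands)
    ]
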