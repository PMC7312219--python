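"""Synthetic two-class multichannel EEG-like epoch generator.

Produces balanced seizure / seizure-free epoch sets in which the
class-discriminative rhythm is confined to a known subset of channels,
so the whole downstream pipeline (decomposition, features, subset
search) can be exercised and validated without any recorded data.

Background activity is pink (1/f) noise plus a weak 10 Hz "alpha"
sinusoid; the seizure surrogate is a sharpened 3 Hz spike-wave added to
the informative channels only, scaled so that its RMS is ``snr`` times
the background RMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epochs import EpochSet

__all__ = ["SynthConfig", "pink_noise", "spike_wave", "generate_epochs"]

#: relative RMS of the 10 Hz background sinusoid w.r.t. the pink noise
_ALPHA_REL_RMS = 0.3
_ALPHA_HZ = 10.0


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic epoch generator."""

    n_channels: int
    informative_channels: frozenset[int] = field(default_factory=frozenset)
    n_per_class: int = 40
    fs: float = 128.0
    duration_s: float = 6.0
    snr: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be positive")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        info = frozenset(self.informative_channels)
        object.__setattr__(self, "informative_channels", info)
        if info and not info <= set(range(self.n_channels)):
            raise ValueError("informative_channels outside 0..n_channels-1")
        n = self.fs * self.duration_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * duration_s must be an integer sample count")
        if self.snr > 0 and not info:
            raise ValueError("informative_channels empty but snr > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


def pink_noise(n_samples: int, seed: int) -> np.ndarray:
    """Zero-mean noise with ~1/f power spectral density.

    Generated by shaping the spectrum of white Gaussian noise with
    1/sqrt(f); deterministic for a given ``seed``.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.empty_like(freqs)
    scale[0] = 0.0  # kill DC -> zero mean
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spectrum * scale, n=n_samples)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def spike_wave(fs: float, duration_s: float, f0: float = 3.0, phase: float = 0.0) -> np.ndarray:
    """Periodic spike-wave surrogate: a cubed sinusoid at ``f0`` Hz.

    Cubing sharpens the crests, injecting odd harmonics so that both the
    energy and the fractal-dimension features see a class contrast.
    Peak absolute amplitude is normalized to 1.
    """
    if not 0 < f0 < fs / 2:
        raise ValueError(f"f0={f0} must lie in (0, fs/2) to avoid aliasing")
    n = int(round(fs * duration_s))
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * f0 * t + phase) ** 3
    return x / np.max(np.abs(x))


def _epoch_rng(master_seed: int, counter: int) -> np.random.Generator:
    # counter-keyed substreams: reproducible regardless of generation order
    return np.random.default_rng(np.random.SeedSequence((master_seed, counter)))


def _one_epoch(config: SynthConfig, rng: np.random.Generator, seizure: bool) -> np.ndarray:
    n = config.n_samples
    t = np.arange(n) / config.fs
    data = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        noise_seed = int(rng.integers(0, 2**31 - 1))
        bg = pink_noise(n, noise_seed)
        alpha_phase = rng.uniform(0, 2 * np.pi)
        alpha = np.sin(2 * np.pi * _ALPHA_HZ * t + alpha_phase)
        bg = bg + _ALPHA_REL_RMS * np.sqrt(2) * alpha  # sine RMS = 1/sqrt(2)
        if seizure and config.snr > 0 and ch in config.informative_channels:
            sw_phase = rng.uniform(0, 2 * np.pi)
            sw = spike_wave(config.fs, config.duration_s, phase=sw_phase)
            sw_rms = np.sqrt(np.mean(sw**2))
            bg_rms = np.sqrt(np.mean(bg**2))
            bg = bg + sw * (config.snr * bg_rms / sw_rms)
        data[ch] = bg
    return data


def generate_epochs(config: SynthConfig) -> EpochSet:
    """Generate ``2 * n_per_class`` balanced epochs per the config.

    Class 1 ("seizure") epochs carry the spike-wave surrogate on the
    informative channels; class 0 epochs are background only.  Fully
    deterministic: epoch ``i`` uses the substream ``(seed, i)``.
    """
    n_total = 2 * config.n_per_class
    labels = np.array([0] * config.n_per_class + [1] * config.n_per_class)
    data = np.empty((n_total, config.n_channels, config.n_samples))
    for i in range(n_total):
        rng = _epoch_rng(config.seed, i)
        data[i] = _one_epoch(config, rng, seizure=bool(labels[i]))
    channel_labels = [f"CH{c}" for c in range(config.n_channels)]
    return EpochSet(data=data, labels=labels, fs=config.fs, channel_labels=channel_labels)
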