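"""Minimal EDF (European Data Format) I/O, montage handling, 256->128 Hz
down-sampling and balanced 6-s epoch extraction from seizure annotations.

The reader/writer implements the standard 16-bit EDF layout directly
(fixed-width ASCII header, one record per second, little-endian two's
complement samples) — enough to round-trip our own files and those of
the bipolar scalp montage this pipeline targets.  Seizure annotations
are carried as a two-column CSV (``start_s,end_s``) per recording,
half-open intervals in seconds from file start.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import butter, filtfilt

from .epochs import EpochSet

__all__ = [
    "Recording",
    "SeizureInterval",
    "EdfFormatError",
    "MontageError",
    "EmptyClassError",
    "CHB_MIT_LABELS",
    "load_recording",
    "write_edf",
    "downsample",
    "epoch_and_label",
    "read_intervals",
    "write_intervals",
    "save_epochset",
    "load_epochset",
]

#: the 22-channel bipolar montage used throughout (duplicate electrode
#: pairs with different references are distinct channels)
CHB_MIT_LABELS = (
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1", "FP1-F3", "F3-C3", "C3-P3",
    "P3-O1", "FP2-F4", "F4-C4", "C4-P4", "P4-O2", "FP2-F8", "F8-T8",
    "P8-O2", "FZ-CZ", "CZ-PZ", "P7-T7", "T7-FT9", "FT9-FT10", "FT10-T8",
    "T8-P8",
)


class EdfFormatError(Exception):
    """Raised for malformed or truncated EDF files."""


class MontageError(Exception):
    """Raised when required montage labels are missing from a recording."""


class EmptyClassError(Exception):
    """Raised when a class has no complete epoch window."""


@dataclass
class Recording:
    """A continuous multichannel recording in physical units."""

    channel_labels: list[str]
    fs: float
    signals: np.ndarray  # (n_channels, n_samples)

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if not self.channel_labels:
            raise ValueError("recording needs at least one channel")
        if len(self.channel_labels) != self.signals.shape[0]:
            raise ValueError("one label per signal required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class SeizureInterval:
    """Half-open annotated interval [start_s, end_s) in seconds."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s:
            raise ValueError(f"invalid interval [{self.start_s}, {self.end_s})")


# ---------------------------------------------------------------------------
# EDF read / write

_DIG_MIN, _DIG_MAX = -32768, 32767


def _fmt8(x: float) -> bytes:
    """Format a number into EDF's 8-char ASCII field, round-trippably."""
    for fmt in ("%.8g", "%.7g", "%.6g", "%.5g", "%.4g", "%.3g"):
        s = fmt % x
        if len(s) <= 8:
            return s.ljust(8).encode("ascii")
    raise ValueError(f"cannot format {x} in 8 chars")


def write_edf(recording: Recording, path) -> None:
    """Write a standard 16-bit EDF file (1-second data records).

    The sample count must be an integer multiple of ``fs``.  Non-finite
    samples are rejected.
    """
    if not recording.channel_labels:
        raise ValueError("recording has no channels")
    sig = recording.signals
    if not np.all(np.isfinite(sig)):
        raise ValueError("signals contain non-finite samples")
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("only integer sampling rates are supported")
    fs = int(round(fs))
    n = recording.n_samples
    if n % fs:
        raise ValueError("sample count must be a whole number of seconds")
    n_records = n // fs
    ns = len(recording.channel_labels)

    pmins, pmaxs, digital = [], [], []
    for ch in range(ns):
        x = sig[ch]
        pmin, pmax = float(x.min()), float(x.max())
        if pmax == pmin:
            pmax = pmin + 1.0
        # parse back the formatted header values so quantization and
        # header agree exactly (write/read/write idempotence)
        pmin = float(_fmt8(pmin))
        pmax = float(_fmt8(pmax))
        gain = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
        d = np.round((x - pmin) / gain + _DIG_MIN)
        digital.append(np.clip(d, _DIG_MIN, _DIG_MAX).astype("<i2"))
        pmins.append(pmin)
        pmaxs.append(pmax)

    header_bytes = 256 + 256 * ns
    h = b""
    h += b"0".ljust(8)
    h += b"X X X X".ljust(80)            # patient id
    h += b"Startdate X X X X".ljust(80)  # recording id
    h += b"01.01.00"                     # fixed date: deterministic output
    h += b"00.00.00"
    h += str(header_bytes).ljust(8).encode()
    h += b"".ljust(44)
    h += str(n_records).ljust(8).encode()
    h += b"1".ljust(8)                   # record duration, seconds
    h += str(ns).ljust(4).encode()

    def field(values, width):
        return b"".join(str(v)[:width].ljust(width).encode("ascii") for v in values)

    h += field(recording.channel_labels, 16)
    h += field([""] * ns, 80)            # transducer
    h += field(["uV"] * ns, 8)
    h += b"".join(_fmt8(p) for p in pmins)
    h += b"".join(_fmt8(p) for p in pmaxs)
    h += field([_DIG_MIN] * ns, 8)
    h += field([_DIG_MAX] * ns, 8)
    h += field([""] * ns, 80)            # prefiltering
    h += field([fs] * ns, 8)
    h += field([""] * ns, 32)
    assert len(h) == header_bytes

    with open(path, "wb") as fh:
        fh.write(h)
        for rec in range(n_records):
            for ch in range(ns):
                fh.write(digital[ch][rec * fs:(rec + 1) * fs].tobytes())


def load_recording(path, require_labels=None) -> Recording:
    """Read an EDF file into physical units, labels in file order.

    ``require_labels`` optionally names montage labels that must all be
    present; missing ones raise :class:`MontageError`.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise EdfFormatError(f"{path}: header truncated")

    def ascii_field(start, width):
        try:
            return raw[start:start + width].decode("ascii").strip()
        except UnicodeDecodeError as exc:
            raise EdfFormatError(f"{path}: non-ASCII header field") from exc

    try:
        header_bytes = int(ascii_field(184, 8))
        n_records = int(ascii_field(236, 8))
        record_dur = float(ascii_field(244, 8))
        ns = int(ascii_field(252, 4))
    except ValueError as exc:
        raise EdfFormatError(f"{path}: malformed header: {exc}") from exc
    if ns < 1 or n_records < 0 or len(raw) < header_bytes:
        raise EdfFormatError(f"{path}: inconsistent header")

    def sig_fields(offset, width, conv):
        base = 256 + offset * ns
        out = []
        for ch in range(ns):
            txt = ascii_field(base + ch * width, width)
            try:
                out.append(conv(txt))
            except ValueError as exc:
                raise EdfFormatError(f"{path}: bad signal header field {txt!r}") from exc
        return out

    labels = sig_fields(0, 16, str)
    # field offsets within the per-signal header block, in bytes-per-signal
    # units: label 16, transducer 80, dim 8, pmin 8, pmax 8, dmin 8, dmax 8,
    # prefilter 80, samples-per-record 8, reserved 32
    off = {"pmin": 16 + 80 + 8, "pmax": 16 + 80 + 16, "dmin": 16 + 80 + 24,
           "dmax": 16 + 80 + 32, "spr": 16 + 80 + 40 + 80}
    pmins = sig_fields(off["pmin"], 8, float)
    pmaxs = sig_fields(off["pmax"], 8, float)
    dmins = sig_fields(off["dmin"], 8, int)
    dmaxs = sig_fields(off["dmax"], 8, int)
    sprs = sig_fields(off["spr"], 8, int)

    record_words = sum(sprs)
    expected = header_bytes + 2 * record_words * n_records
    if len(raw) < expected:
        raise EdfFormatError(f"{path}: data truncated ({len(raw)} < {expected} bytes)")

    data = np.frombuffer(raw[header_bytes:expected], dtype="<i2")
    signals = [np.empty(sprs[ch] * n_records) for ch in range(ns)]
    pos = 0
    for rec in range(n_records):
        for ch in range(ns):
            chunk = data[pos:pos + sprs[ch]]
            pos += sprs[ch]
            gain = (pmaxs[ch] - pmins[ch]) / (dmaxs[ch] - dmins[ch])
            signals[ch][rec * sprs[ch]:(rec + 1) * sprs[ch]] = (
                (chunk.astype(float) - dmins[ch]) * gain + pmins[ch]
            )
    if len(set(sprs)) != 1:
        raise EdfFormatError(f"{path}: mixed per-signal rates unsupported")
    fs = sprs[0] / record_dur
    recording = Recording(channel_labels=labels, fs=fs, signals=np.vstack(signals))
    if require_labels is not None:
        missing = [lb for lb in require_labels if lb not in labels]
        if missing:
            raise MontageError(f"{path}: montage labels missing: {missing}")
    return recording


# ---------------------------------------------------------------------------
# down-sampling and epoching


def downsample(signal: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased integer-factor decimation (zero-phase low-pass at
    0.45 * fs_out, then keep every ``fs_in/fs_out``-th sample)."""
    x = np.asarray(signal, dtype=float)
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"fs_in={fs_in} must be an integer multiple of fs_out={fs_out}")
    q = int(round(ratio))
    if q == 1:
        return x.copy()
    cutoff = 0.45 * fs_out
    b, a = butter(8, cutoff / (fs_in / 2))
    filtered = filtfilt(b, a, x)
    out_len = int(x.size * fs_out // fs_in)
    return filtered[::q][:out_len]


def _window_starts(intervals, n_samples, fs, epoch_s, exclusion_margin_s=0.0):
    """(seizure_starts, free_starts) as sample indices of complete windows."""
    win = int(round(epoch_s * fs))
    seiz = []
    for iv in intervals:
        s0 = int(round(iv.start_s * fs))
        s1 = int(round(iv.end_s * fs))
        pos = s0
        while pos + win <= s1:
            seiz.append(pos)
            pos += win
    free = []
    margin = int(round(exclusion_margin_s * fs))
    pos = 0
    while pos + win <= n_samples:
        overlaps = any(
            pos < int(round(iv.end_s * fs)) + margin
            and pos + win > int(round(iv.start_s * fs)) - margin
            for iv in intervals
        )
        if not overlaps:
            free.append(pos)
        pos += win
    return seiz, free


def epoch_and_label(
    recording: Recording,
    intervals: list[SeizureInterval],
    epoch_s: float = 6.0,
    seed: int = 0,
    exclusion_margin_s: float = 0.0,
) -> EpochSet:
    """Cut balanced seizure / seizure-free epochs from a recording.

    Seizure epochs are the non-overlapping complete ``epoch_s`` windows
    inside the annotated intervals; an equal number of seizure-free
    windows is drawn (seeded, without replacement) from the 6-s grid
    positions fully outside every interval.  No epoch ever straddles an
    interval boundary.
    """
    win = epoch_s * recording.fs
    if abs(win - round(win)) > 1e-9:
        raise ValueError("epoch_s * fs must be an integer sample count")
    win = int(round(win))
    for iv in intervals:
        if iv.end_s > recording.duration_s + 1e-9:
            raise ValueError(f"interval {iv} extends beyond the recording")
    seiz_starts, free_starts = _window_starts(
        intervals, recording.n_samples, recording.fs, epoch_s, exclusion_margin_s
    )
    if not seiz_starts:
        raise EmptyClassError("no complete seizure window in any interval")
    if len(free_starts) < len(seiz_starts):
        raise EmptyClassError(
            f"cannot balance: {len(seiz_starts)} seizure vs {len(free_starts)} free windows"
        )
    rng = np.random.default_rng(seed)
    chosen_free = sorted(rng.choice(free_starts, size=len(seiz_starts), replace=False))
    data, labels = [], []
    for pos in chosen_free:
        data.append(recording.signals[:, pos:pos + win])
        labels.append(0)
    for pos in seiz_starts:
        data.append(recording.signals[:, pos:pos + win])
        labels.append(1)
    return EpochSet(
        data=np.stack(data),
        labels=np.array(labels),
        fs=recording.fs,
        channel_labels=list(recording.channel_labels),
    )


# ---------------------------------------------------------------------------
# annotation CSV and epoch-set directory serialization


def read_intervals(path) -> list[SeizureInterval]:
    """Read seizure intervals from a two-column ``start_s,end_s`` CSV."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row or row[0].strip().lower() in ("start_s", "#"):
                continue
            out.append(SeizureInterval(float(row[0]), float(row[1])))
    return out


def write_intervals(intervals: list[SeizureInterval], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["start_s", "end_s"])
        for iv in intervals:
            writer.writerow([iv.start_s, iv.end_s])


def save_epochset(epochs: EpochSet, directory) -> None:
    """Serialize an epoch set as one EDF per class plus a labels CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cls in (0, 1):
        idx = np.flatnonzero(epochs.labels == cls)
        if idx.size == 0:
            continue
        concat = np.concatenate([epochs.data[i] for i in idx], axis=1)
        rec = Recording(list(epochs.channel_labels), epochs.fs, concat)
        write_edf(rec, directory / f"class{cls}.edf")
    with open(directory / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "count", "epoch_samples"])
        for cls in (0, 1):
            writer.writerow([cls, int(np.sum(epochs.labels == cls)), epochs.n_samples])


def load_epochset(directory) -> EpochSet:
    directory = Path(directory)
    counts = {}
    n_samples = None
    with open(directory / "labels.csv", newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            counts[int(row["label"])] = int(row["count"])
            n_samples = int(row["epoch_samples"])
    data, labels = [], []
    fs = None
    channel_labels = None
    for cls in (0, 1):
        if counts.get(cls, 0) == 0:
            continue
        rec = load_recording(directory / f"class{cls}.edf")
        fs = rec.fs
        channel_labels = rec.channel_labels
        for i in range(counts[cls]):
            data.append(rec.signals[:, i * n_samples:(i + 1) * n_samples])
            labels.append(cls)
    return EpochSet(np.stack(data), np.array(labels), fs, list(channel_labels))
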