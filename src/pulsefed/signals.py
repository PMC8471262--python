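"""Segmentation, min-max normalization and dataset plumbing.

Signals are segmented into fixed-length non-overlapping windows (8 s at
125 Hz for training-style data, 10 s at 100 Hz for test-style data; both
give 1000-sample segments and the model is defined on sample index, so no
resampling is performed).  Each segment is min-max normalized to [0, 1]
independently; the original (min, max) pair is kept so the map is
invertible.  Generated ABP is mapped back to mmHg with a normalization
record built from the ABP statistics of the training dataset, since at
inference time only PPG is observed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .simulate import SegmentPair

__all__ = [
    "Waveform",
    "NormalizationRecord",
    "DegenerateSegmentError",
    "segment_signal",
    "minmax_normalize",
    "denormalize",
    "normalize_pairs",
    "dataset_abp_record",
    "read_text_waveform",
    "write_text_waveform",
]


class DegenerateSegmentError(ValueError):
    """Raised for a constant (flat-line) segment that cannot be normalized."""


@dataclass(frozen=True)
class Waveform:
    """A single-channel signal with its sampling rate and units."""

    samples: np.ndarray
    fs_hz: float
    modality: str = "PPG"        # "PPG" | "ABP"
    units: str = "a.u."          # "a.u." | "mmHg" | "normalized"

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")


@dataclass(frozen=True)
class NormalizationRecord:
    """Original (min, max) of a segment; inverts min-max normalization."""

    min_val: float
    max_val: float

    def __post_init__(self):
        if not (self.max_val > self.min_val):
            raise ValueError(
                f"max_val must exceed min_val, got ({self.min_val}, {self.max_val})"
            )


def segment_signal(signal: Waveform, window_s: float) -> list[Waveform]:
    """Split into consecutive non-overlapping windows of ``window_s`` seconds.

    The window must correspond to a whole number of samples (>= 2).  The
    trailing remainder is discarded; a window longer than the signal
    yields an empty list.
    """
    n_win = window_s * signal.fs_hz
    if abs(n_win - round(n_win)) > 1e-9 or round(n_win) < 2:
        raise ValueError(
            f"window_s * fs_hz must be a whole number >= 2, got {n_win}"
        )
    n_win = int(round(n_win))
    n_seg = len(signal.samples) // n_win
    return [
        replace(signal, samples=signal.samples[k * n_win : (k + 1) * n_win])
        for k in range(n_seg)
    ]


def minmax_normalize(segment: Waveform) -> tuple[Waveform, NormalizationRecord]:
    """Scale a segment to [0, 1] exactly; returns the inverse-map record."""
    x = segment.samples
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise DegenerateSegmentError(
            "constant segment cannot be min-max normalized (flat-line artifact)"
        )
    y = (x - lo) / (hi - lo)
    return replace(segment, samples=y, units="normalized"), NormalizationRecord(lo, hi)


def denormalize(segment: Waveform, record: NormalizationRecord) -> Waveform:
    """Invert :func:`minmax_normalize` with the stored record."""
    if segment.units != "normalized":
        raise ValueError(f"expected normalized units, got {segment.units!r}")
    y = segment.samples * (record.max_val - record.min_val) + record.min_val
    units = "mmHg" if segment.modality == "ABP" else "a.u."
    return replace(segment, samples=y, units=units)


def _norm01(x: np.ndarray) -> np.ndarray:
    lo = x.min()
    hi = x.max()
    if hi <= lo:
        raise DegenerateSegmentError("constant segment in dataset")
    return (x - lo) / (hi - lo)


def normalize_pairs(pairs: Sequence[SegmentPair]) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment min-max normalize a paired dataset.

    Returns float32 arrays ``(ppg, abp)`` of shape (n_segments, seg_len),
    the form consumed by training.
    """
    ppg = np.stack([_norm01(np.asarray(p.ppg, dtype=np.float64)) for p in pairs])
    abp = np.stack([_norm01(np.asarray(p.abp, dtype=np.float64)) for p in pairs])
    return ppg.astype(np.float32), abp.astype(np.float32)


def dataset_abp_record(pairs: Sequence[SegmentPair]) -> NormalizationRecord:
    """Global ABP (min, max) over a training dataset, in mmHg.

    Used to map generated normalized ABP back to pressure units at
    inference, where no per-segment ABP reference exists.
    """
    lo = min(float(np.min(p.abp)) for p in pairs)
    hi = max(float(np.max(p.abp)) for p in pairs)
    return NormalizationRecord(lo, hi)


def read_text_waveform(path) -> Waveform:
    """Read a single-channel delimited-text waveform.

    Format: a header line ``# fs_hz=<rate> modality=<PPG|ABP> units=<u>``
    followed by one sample per line.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '# fs_hz=...' header line")
        fields = dict(item.split("=", 1) for item in header[1:].split())
        samples = np.loadtxt(fh, dtype=float, ndmin=1)
    return Waveform(
        samples=samples,
        fs_hz=float(fields["fs_hz"]),
        modality=fields.get("modality", "PPG"),
        units=fields.get("units", "a.u."),
    )


def write_text_waveform(path, waveform: Waveform) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={waveform.fs_hz} modality={waveform.modality} "
                 f"units={waveform.units}\n")
        np.savetxt(fh, waveform.samples, fmt="%.8g")
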