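"""Blood-pressure evaluation of generated ABP waveforms.

Per segment: systolic/diastolic extraction from detected beats, mean
arterial pressure MAP = [SBP + 2*DBP] / 3, and waveform-similarity
metrics (DTW, RMSE, Pearson correlation) computed on min-max normalized
traces.  Per dataset: Bland-Altman agreement of estimated vs true MAP
(mean error mu, SD sigma, 95% limits of agreement mu +/- 1.96 sigma),
the AAMI verdict (|mu| < 5 mmHg and sigma < 8 mmHg), and an optional
additive-offset calibration estimated on an initial time window and
applied to — and assessed on — the remainder.

MAP is computed from detected systolic peaks and diastolic troughs, not
from the arithmetic mean of the trace: for asymmetric pulse shapes the
two differ, and the peak-based definition is the clinically reported one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as _scipy_signal
from scipy import stats as _scipy_stats

__all__ = [
    "BeatPressures",
    "BlandAltmanResult",
    "SimilarityMetrics",
    "EvaluationReport",
    "NoBeatsError",
    "extract_sbp_dbp",
    "compute_map",
    "bland_altman",
    "calibrate",
    "dtw_distance",
    "rmse",
    "pearson_cc",
    "evaluate_dataset",
]

AAMI_MEAN_LIMIT_MMHG = 5.0
AAMI_SD_LIMIT_MMHG = 8.0
_MAX_HR_BPM = 180.0          # minimum peak separation assumes HR <= 180
_PROMINENCE_FRAC = 0.10      # peak prominence, fraction of segment range


class NoBeatsError(ValueError):
    """Fewer than one beat detected in a segment."""


@dataclass(frozen=True)
class BeatPressures:
    """Per-segment systolic/diastolic/mean arterial pressure, mmHg."""

    sbp: float
    dbp: float
    map: float

    def __post_init__(self):
        if not (self.sbp >= self.map >= self.dbp):
            raise ValueError(
                f"pressure ordering violated: sbp={self.sbp}, map={self.map}, dbp={self.dbp}"
            )


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement statistics of estimated - true MAP, mmHg."""

    mu: float
    sigma: float
    loa_low: float
    loa_high: float
    aami_pass: bool
    n: int


@dataclass(frozen=True)
class SimilarityMetrics:
    """Waveform similarity on normalized traces (segment averages)."""

    dtw: float
    rmse: float
    pcc: float

    def __post_init__(self):
        if self.dtw < 0 or self.rmse < 0 or not (-1.0 - 1e-9 <= self.pcc <= 1.0 + 1e-9):
            raise ValueError(f"invalid similarity metrics: {self}")


@dataclass(frozen=True)
class EvaluationReport:
    """Dataset-level evaluation: similarity metrics + Bland-Altman blocks."""

    similarity: SimilarityMetrics
    bland_altman: BlandAltmanResult
    bland_altman_calibrated: BlandAltmanResult | None
    n_segments: int
    n_evaluated: int
    n_failed: int
    per_segment: pd.DataFrame

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.per_segment.to_csv(directory / "per_segment.csv", index=False)
        lines = [
            f"n_segments\t{self.n_segments}",
            f"n_evaluated\t{self.n_evaluated}",
            f"n_failed\t{self.n_failed}",
            f"dtw\t{self.similarity.dtw:.6g}",
            f"rmse\t{self.similarity.rmse:.6g}",
            f"pcc\t{self.similarity.pcc:.6g}",
        ]
        for tag, ba in (("", self.bland_altman), ("cal_", self.bland_altman_calibrated)):
            if ba is None:
                continue
            lines += [
                f"{tag}mu_mmhg\t{ba.mu:.6g}",
                f"{tag}sigma_mmhg\t{ba.sigma:.6g}",
                f"{tag}loa_low_mmhg\t{ba.loa_low:.6g}",
                f"{tag}loa_high_mmhg\t{ba.loa_high:.6g}",
                f"{tag}aami_pass\t{ba.aami_pass}",
                f"{tag}n\t{ba.n}",
            ]
        (directory / "summary.tsv").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# per-segment pressures
# ---------------------------------------------------------------------------

def compute_map(sbp: float, dbp: float) -> float:
    """Mean arterial pressure, [SBP + 2*DBP] / 3."""
    if sbp < dbp:
        raise ValueError(f"sbp must be >= dbp, got sbp={sbp}, dbp={dbp}")
    return (sbp + 2.0 * dbp) / 3.0


def _detect_extrema(x: np.ndarray, fs_hz: float) -> tuple[np.ndarray, np.ndarray]:
    rng_x = float(x.max() - x.min())
    if rng_x <= 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    min_dist = max(1, int(fs_hz * 60.0 / _MAX_HR_BPM))
    prom = _PROMINENCE_FRAC * rng_x
    peaks, _ = _scipy_signal.find_peaks(x, distance=min_dist, prominence=prom)
    troughs, _ = _scipy_signal.find_peaks(-x, distance=min_dist, prominence=prom)
    return peaks, troughs


def extract_sbp_dbp(abp: np.ndarray, fs_hz: float) -> BeatPressures:
    """SBP/DBP/MAP from an ABP segment (mmHg) via beat extrema detection.

    SBP is the mean of detected systolic peak amplitudes, DBP the mean of
    detected trough amplitudes.  Requires at least one peak and one
    trough, else :class:`NoBeatsError`.
    """
    x = np.asarray(abp, dtype=float)
    if len(x) < 2 * fs_hz:
        raise ValueError(f"segment must be at least 2 s long, got {len(x) / fs_hz:.2f} s")
    peaks, troughs = _detect_extrema(x, fs_hz)
    if len(peaks) < 1 or len(troughs) < 1:
        raise NoBeatsError("no beats detected in segment")
    sbp = float(np.mean(x[peaks]))
    dbp = float(np.mean(x[troughs]))
    return BeatPressures(sbp=sbp, dbp=dbp, map=compute_map(sbp, dbp))


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

def bland_altman(true_map: Sequence[float], est_map: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman statistics of the per-segment MAP error (est - true).

    ``sigma`` uses the sample (n-1) denominator; limits of agreement are
    mu +/- 1.96 sigma; the AAMI verdict requires |mu| < 5 and sigma < 8.
    """
    t = np.asarray(true_map, dtype=float)
    e = np.asarray(est_map, dtype=float)
    if t.shape != e.shape or t.ndim != 1 or len(t) < 2:
        raise ValueError(f"need equal-length 1-D sequences of n >= 2, got {t.shape}, {e.shape}")
    err = e - t
    mu = float(np.mean(err))
    sigma = float(np.std(err, ddof=1))
    return BlandAltmanResult(
        mu=mu,
        sigma=sigma,
        loa_low=mu - 1.96 * sigma,
        loa_high=mu + 1.96 * sigma,
        aami_pass=bool(abs(mu) < AAMI_MEAN_LIMIT_MMHG and sigma < AAMI_SD_LIMIT_MMHG),
        n=len(err),
    )


def calibrate(est_map: Sequence[float], true_map: Sequence[float],
              cal_duration_s: float, segment_duration_s: float,
              ) -> tuple[np.ndarray, np.ndarray, int]:
    """Additive-offset calibration on an initial time window.

    The offset is the mean (est - true) over the first
    ``cal_duration_s // segment_duration_s`` segments; it is subtracted
    from all subsequent estimates.  Returns (calibrated estimates, true
    values, n_cal) for the post-calibration period only — calibration
    segments are excluded from downstream statistics.
    """
    e = np.asarray(est_map, dtype=float)
    t = np.asarray(true_map, dtype=float)
    if e.shape != t.shape or e.ndim != 1:
        raise ValueError("est_map and true_map must be equal-length 1-D sequences")
    n_cal = int(cal_duration_s // segment_duration_s)
    if n_cal < 1:
        raise ValueError(
            f"calibration window ({cal_duration_s} s) shorter than one segment "
            f"({segment_duration_s} s)"
        )
    if n_cal >= len(e):
        raise ValueError("calibration window covers the whole dataset")
    offset = float(np.mean(e[:n_cal] - t[:n_cal]))
    return e[n_cal:] - offset, t[n_cal:], n_cal


# ---------------------------------------------------------------------------
# similarity metrics
# ---------------------------------------------------------------------------

def dtw_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Classic unconstrained DTW distance with |.| local cost.

    Steps {match, insert, delete}; returns the optimal cumulative path
    cost between the two sequences.
    """
    from ._dtw_kernel import dtw_kernel

    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.ndim != 1 or b.ndim != 1 or len(a) == 0 or len(b) == 0:
        raise ValueError("dtw_distance requires two non-empty 1-D sequences")
    return float(dtw_kernel(a, b))


def rmse(a: Sequence[float], b: Sequence[float]) -> float:
    """Root-mean-squared error between equal-length sequences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError(f"need equal-length sequences, got {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def pearson_cc(a: Sequence[float], b: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError(f"need equal-length sequences of n >= 2, got {a.shape} vs {b.shape}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(_scipy_stats.pearsonr(a, b).statistic)


def _norm01(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    return (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)


# ---------------------------------------------------------------------------
# dataset-level evaluation
# ---------------------------------------------------------------------------

def evaluate_dataset(real_abp: Sequence[np.ndarray], gen_abp: Sequence[np.ndarray],
                     fs_hz: float, cal_duration_s: float = 0.0) -> EvaluationReport:
    """Evaluate generated against real ABP segments (both in mmHg).

    Similarity metrics are computed per segment on min-max normalized
    traces and averaged; Bland-Altman statistics are computed over
    per-segment MAP values.  Segments where beat detection fails in
    either trace are excluded and counted.  When ``cal_duration_s`` > 0 a
    calibrated Bland-Altman block (initial-window offset removal) is also
    produced.
    """
    if len(real_abp) == 0 or len(real_abp) != len(gen_abp):
        raise ValueError("need equal, non-zero numbers of real and generated segments")
    rows = []
    for k, (r, g) in enumerate(zip(real_abp, gen_abp)):
        r = np.asarray(r, dtype=float)
        g = np.asarray(g, dtype=float)
        row: dict = {"segment": k}
        try:
            bp_r = extract_sbp_dbp(r, fs_hz)
            bp_g = extract_sbp_dbp(g, fs_hz)
        except NoBeatsError:
            row["ok"] = False
            rows.append(row)
            continue
        rn, gn = _norm01(r), _norm01(g)
        row.update(
            ok=True,
            true_sbp=bp_r.sbp, true_dbp=bp_r.dbp, true_map=bp_r.map,
            est_sbp=bp_g.sbp, est_dbp=bp_g.dbp, est_map=bp_g.map,
            dtw=dtw_distance(rn, gn),
            rmse=rmse(rn, gn),
            pcc=pearson_cc(rn, gn),
        )
        rows.append(row)
    per_segment = pd.DataFrame(rows)
    ok = per_segment[per_segment["ok"]] if "ok" in per_segment else per_segment
    n_failed = int(len(per_segment) - len(ok))
    if len(ok) == 0:
        raise ValueError("beat detection failed on every segment")
    similarity = SimilarityMetrics(
        dtw=float(ok["dtw"].mean()),
        rmse=float(ok["rmse"].mean()),
        pcc=float(ok["pcc"].mean()),
    )
    ba = bland_altman(ok["true_map"].to_numpy(), ok["est_map"].to_numpy())
    ba_cal = None
    if cal_duration_s > 0:
        seg_dur = len(np.asarray(real_abp[0])) / fs_hz
        est_c, true_c, _ = calibrate(ok["est_map"].to_numpy(), ok["true_map"].to_numpy(),
                                     cal_duration_s, seg_dur)
        ba_cal = bland_altman(true_c, est_c)
    return EvaluationReport(
        similarity=similarity,
        bland_altman=ba,
        bland_altman_calibrated=ba_cal,
        n_segments=len(per_segment),
        n_evaluated=len(ok) if ba_cal is None else ba_cal.n,
        n_failed=n_failed,
        per_segment=per_segment,
    )


def bland_altman_figure(true_map: Sequence[float], est_map: Sequence[float], path) -> None:
    """Save a Bland-Altman scatter (mean vs difference) figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.asarray(true_map, dtype=float)
    e = np.asarray(est_map, dtype=float)
    res = bland_altman(t, e)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter((t + e) / 2.0, e - t, s=8, alpha=0.5)
    for y, style in ((res.mu, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean MAP (mmHg)")
    ax.set_ylabel("estimated - true MAP (mmHg)")
    ax.set_title(f"Bland-Altman: mu={res.mu:.2f}, sigma={res.sigma:.2f} mmHg")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
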