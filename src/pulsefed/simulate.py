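"""Synthetic paired PPG/ABP segment generator.

Produces quasi-periodic pulse waveforms with known ground-truth systolic
and diastolic pressures and a deterministic, invertible PPG -> ABP
coupling, so the translation model and the blood-pressure evaluation
pipeline can be exercised end to end without any recorded data.

Model
-----
Each beat is the sum of two smooth Gaussian bumps (systolic peak plus a
dicrotic wave), with channel-specific morphologies: the PPG pulse is
broad and rounded, the ABP pulse has a sharp systolic upstroke and a
prominent dicrotic wave.  Both channels share the same beat-onset train
(one onset anchored at t = 0; intervals carry i.i.d. Gaussian jitter
truncated at +/-3 SD), and the ABP is additionally delayed by the pulse
transit time, so the PPG -> ABP coupling is deterministic and
invertible.  The PPG channel carries multiplicative respiratory
amplitude modulation, additive sinusoidal baseline wander and white
Gaussian noise.  The ABP template is affinely rescaled so that every
noiseless beat peaks at the target systolic pressure and the segment
minimum is the diastolic pressure; wander and noise (scaled by pulse
pressure) are added after rescaling.

This emulates the statistical structure of paired cuff-less BP recordings
(fixed-length windows, two aligned channels, per-segment SBP/DBP ground
truth); it makes no claim of hemodynamic realism.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "SegmentPair",
    "PerSegmentVariation",
    "SimulationParameterError",
    "simulate_pair",
    "make_dataset",
    "save_dataset",
    "load_dataset",
]

# Beat morphologies as (center, width, amplitude) Gaussian bumps, all in
# fractions of the beat interval.  The two channels share beat onsets (and
# the ABP is additionally delayed by the pulse transit time) but have
# distinct pulse shapes, as real signals do: PPG is a broad rounded pulse
# with a weak late dicrotic hump, ABP has a sharp systolic upstroke and a
# prominent dicrotic wave.
_PPG_MORPH = ((0.22, 0.13, 1.0), (0.45, 0.16, 0.25))
_ABP_MORPH = ((0.12, 0.07, 1.0), (0.35, 0.09, 0.35))
_RESP_MOD_DEPTH = 0.03
_WANDER_HZ = 0.2


class SimulationParameterError(ValueError):
    """A simulation parameter violates its physiological/structural bounds."""

    def __init__(self, field: str, message: str):
        super().__init__(f"{field}: {message}")
        self.field = field


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated segment pair.

    hr_bpm : mean heart rate, beats/min
    hr_jitter_pct : fractional SD of the beat interval (0.03 = 3%)
    sbp_mmhg, dbp_mmhg : target systolic/diastolic pressure, mmHg
    ptt_s : PPG-to-ABP pulse transit delay, s
    noise_sd : additive white-noise SD as a fraction of pulse amplitude
    drift_amp : baseline-wander amplitude as a fraction of pulse amplitude
    resp_rate_bpm : respiratory amplitude-modulation rate, breaths/min
    fs_hz : sampling rate, Hz
    seg_len_samples : samples per segment
    seed : RNG seed
    """

    hr_bpm: float = 60.0
    hr_jitter_pct: float = 0.03
    sbp_mmhg: float = 120.0
    dbp_mmhg: float = 80.0
    ptt_s: float = 0.2
    noise_sd: float = 0.02
    drift_amp: float = 0.01
    resp_rate_bpm: float = 15.0
    fs_hz: float = 125.0
    seg_len_samples: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not (self.sbp_mmhg > self.dbp_mmhg > 0):
            raise SimulationParameterError(
                "sbp_mmhg/dbp_mmhg",
                f"need sbp > dbp > 0, got sbp={self.sbp_mmhg}, dbp={self.dbp_mmhg}",
            )
        if not (30.0 <= self.hr_bpm <= 220.0):
            raise SimulationParameterError("hr_bpm", f"must be in [30, 220], got {self.hr_bpm}")
        if self.fs_hz <= 0:
            raise SimulationParameterError("fs_hz", f"must be positive, got {self.fs_hz}")
        if self.seg_len_samples <= 0:
            raise SimulationParameterError(
                "seg_len_samples", f"must be positive, got {self.seg_len_samples}"
            )
        if self.noise_sd < 0:
            raise SimulationParameterError("noise_sd", f"must be >= 0, got {self.noise_sd}")
        if self.hr_jitter_pct < 0:
            raise SimulationParameterError(
                "hr_jitter_pct", f"must be >= 0, got {self.hr_jitter_pct}"
            )
        if self.drift_amp < 0:
            raise SimulationParameterError("drift_amp", f"must be >= 0, got {self.drift_amp}")
        if self.ptt_s < 0:
            raise SimulationParameterError("ptt_s", f"must be >= 0, got {self.ptt_s}")
        if self.resp_rate_bpm < 0:
            raise SimulationParameterError(
                "resp_rate_bpm", f"must be >= 0, got {self.resp_rate_bpm}"
            )


@dataclass(frozen=True)
class SegmentPair:
    """One aligned PPG/ABP segment pair with its ground truth."""

    ppg: np.ndarray      # arbitrary units
    abp: np.ndarray      # mmHg
    fs_hz: float
    true_sbp: float
    true_dbp: float

    def __post_init__(self):
        if len(self.ppg) != len(self.abp):
            raise SimulationParameterError(
                "ppg/abp", f"channel lengths differ: {len(self.ppg)} vs {len(self.abp)}"
            )


@dataclass(frozen=True)
class PerSegmentVariation:
    """Gaussian between-segment spread of ground truth (SDs; 0 disables)."""

    sbp_sd: float = 0.0
    dbp_sd: float = 0.0
    hr_sd: float = 0.0


def _beat_onsets(params: SimParams, rng: np.random.Generator,
                 t_min: float, t_max: float) -> tuple[np.ndarray, np.ndarray]:
    """Jittered beat onsets covering [t_min, t_max], anchored at t = 0.

    One beat onset falls exactly at t = 0; intervals accumulate jitter
    outward in both directions, so the anchor itself never drifts.
    """
    mean_ibi = 60.0 / params.hr_bpm

    def _intervals(n: int) -> np.ndarray:
        jit = rng.normal(0.0, params.hr_jitter_pct, size=n)
        np.clip(jit, -3.0 * params.hr_jitter_pct, 3.0 * params.hr_jitter_pct, out=jit)
        return mean_ibi * (1.0 + jit)

    n_back = int(np.ceil(max(0.0, -t_min) / mean_ibi)) + 2
    n_fwd = int(np.ceil(max(0.0, t_max) / mean_ibi)) + 2
    back = _intervals(n_back)
    fwd = _intervals(n_fwd)
    onsets_back = -np.cumsum(back)[::-1]
    onsets_fwd = np.concatenate([[0.0], np.cumsum(fwd[:-1])])
    onsets = np.concatenate([onsets_back, onsets_fwd])
    intervals = np.concatenate([back[::-1], fwd])
    return onsets, intervals


def _pulse_template(t: np.ndarray, onsets: np.ndarray, intervals: np.ndarray,
                    morphology) -> np.ndarray:
    """Sum of per-beat systolic + dicrotic Gaussian bumps evaluated at t."""
    out = np.zeros_like(t)
    for onset, ibi in zip(onsets, intervals):
        for center, width, amp in morphology:
            mu = onset + center * ibi
            sd = width * ibi
            # Gaussian support is effectively +/-4 sd; skip beats far away
            lo = np.searchsorted(t, mu - 4 * sd)
            hi = np.searchsorted(t, mu + 4 * sd)
            if hi > lo:
                out[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - mu) / sd) ** 2)
    return out


def simulate_pair(params: SimParams) -> SegmentPair:
    """Generate one aligned PPG/ABP segment pair.

    The noiseless ABP segment attains ``sbp_mmhg`` at its maximum and
    ``dbp_mmhg`` at its minimum exactly (affine rescaling of the delayed
    beat template).  Identical params (including seed) give bitwise
    identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.seg_len_samples
    t = np.arange(n) / params.fs_hz
    duration = n / params.fs_hz

    # beats start before the window so the first (possibly delayed) beat is
    # complete; segments are beat-aligned (a beat onset falls at t ~= 0, up
    # to accumulated interval jitter), which keeps the PPG->ABP phase
    # relation identifiable from single segments
    onsets, intervals = _beat_onsets(params, rng, -2.0 * 60.0 / params.hr_bpm,
                                     duration + 2.0)

    resp_hz = params.resp_rate_bpm / 60.0
    resp_phase = rng.uniform(0.0, 2.0 * np.pi)
    wander_phase = rng.uniform(0.0, 2.0 * np.pi)

    base = _pulse_template(t, onsets, intervals, _PPG_MORPH)
    resp_mod = 1.0 + _RESP_MOD_DEPTH * np.sin(2.0 * np.pi * resp_hz * t + resp_phase)
    wander = np.sin(2.0 * np.pi * _WANDER_HZ * t + wander_phase)

    ppg_amp = float(base.max() - base.min()) or 1.0
    ppg = base * resp_mod
    ppg = ppg + params.drift_amp * ppg_amp * wander
    ppg = ppg + rng.normal(0.0, params.noise_sd * ppg_amp, size=n)

    # ABP: same template delayed by the pulse transit time, then affinely
    # mapped so the noiseless segment spans [dbp, sbp]; respiratory
    # amplitude modulation is a peripheral (PPG) effect and is not applied
    # here, so every noiseless beat peaks at sbp
    abp_tmpl = _pulse_template(t - params.ptt_s, onsets, intervals, _ABP_MORPH)
    lo, hi = float(abp_tmpl.min()), float(abp_tmpl.max())
    if hi <= lo:
        raise SimulationParameterError("seg_len_samples", "segment too short to contain a beat")
    pulse_pressure = params.sbp_mmhg - params.dbp_mmhg
    abp = params.dbp_mmhg + (abp_tmpl - lo) * (pulse_pressure / (hi - lo))
    abp = abp + params.drift_amp * pulse_pressure * wander
    abp = abp + rng.normal(0.0, params.noise_sd * pulse_pressure, size=n)

    return SegmentPair(ppg=ppg, abp=abp, fs_hz=params.fs_hz,
                       true_sbp=params.sbp_mmhg, true_dbp=params.dbp_mmhg)


def make_dataset(params: SimParams, n_segments: int,
                 variation: PerSegmentVariation | None = None) -> list[SegmentPair]:
    """Generate ``n_segments`` pairs with optional between-segment variation.

    Each segment records its own ground truth.  Reproducible from
    ``params.seed``; per-segment streams are spawned so segments are
    independent.
    """
    if n_segments < 1:
        raise SimulationParameterError("n_segments", f"must be >= 1, got {n_segments}")
    params.validate()
    variation = variation or PerSegmentVariation()
    meta_rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 977]))
    pairs: list[SegmentPair] = []
    for k in range(n_segments):
        sbp = params.sbp_mmhg + (meta_rng.normal(0.0, variation.sbp_sd) if variation.sbp_sd else 0.0)
        dbp = params.dbp_mmhg + (meta_rng.normal(0.0, variation.dbp_sd) if variation.dbp_sd else 0.0)
        hr = params.hr_bpm + (meta_rng.normal(0.0, variation.hr_sd) if variation.hr_sd else 0.0)
        # keep draws physiological and ordered
        hr = float(np.clip(hr, 30.0, 220.0))
        if sbp - dbp < 10.0:
            mid = 0.5 * (sbp + dbp)
            sbp, dbp = mid + 5.0, mid - 5.0
        seg_params = dataclasses.replace(
            params, sbp_mmhg=float(sbp), dbp_mmhg=float(dbp), hr_bpm=hr,
            seed=int(np.random.SeedSequence([int(params.seed), 31, k]).generate_state(1)[0]
                     % (2 ** 31)),
        )
        pairs.append(simulate_pair(seg_params))
    return pairs


def to_array(pairs: Sequence[SegmentPair]) -> np.ndarray:
    """Stack pairs into an (n_segments, 2, seg_len) array, channels [PPG, ABP]."""
    return np.stack([np.stack([p.ppg, p.abp]) for p in pairs])


def save_dataset(directory, pairs: Sequence[SegmentPair], seed: int | None = None) -> None:
    """Write ``dataset.npz`` (array container) + ``manifest.csv`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "dataset.npz", segments=to_array(pairs))
    manifest = pd.DataFrame({
        "segment": np.arange(len(pairs)),
        "fs_hz": [p.fs_hz for p in pairs],
        "true_sbp": [p.true_sbp for p in pairs],
        "true_dbp": [p.true_dbp for p in pairs],
    })
    if seed is not None:
        manifest["seed"] = seed
    manifest.to_csv(directory / "manifest.csv", index=False, float_format="%.17g")


def load_dataset(directory) -> list[SegmentPair]:
    """Read a dataset written by :func:`save_dataset`."""
    directory = Path(directory)
    with np.load(directory / "dataset.npz") as data:
        segments = data["segments"]
    manifest = pd.read_csv(directory / "manifest.csv", float_precision="round_trip")
    if segments.ndim != 3 or segments.shape[1] != 2 or len(manifest) != segments.shape[0]:
        raise ValueError(
            f"malformed dataset: array shape {segments.shape}, manifest rows {len(manifest)}"
        )
    return [
        SegmentPair(ppg=segments[k, 0], abp=segments[k, 1],
                    fs_hz=float(row.fs_hz), true_sbp=float(row.true_sbp),
                    true_dbp=float(row.true_dbp))
        for k, row in enumerate(manifest.itertuples())
    ]
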