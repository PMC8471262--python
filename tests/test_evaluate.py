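"""Blood-pressure evaluation: MAP, Bland-Altman, calibration, DTW/RMSE/PCC."""

import dataclasses

import numpy as np
import pytest

from pulsefed import evaluate as ev
from pulsefed.simulate import SimParams, simulate_pair


# --- MAP ------------------------------------------------------------------

@pytest.mark.parametrize("sbp, dbp, expected", [
    (120.0, 80.0, 93.3333333),
    (100.0, 100.0, 100.0),
    (90.0, 60.0, 70.0),
])
def test_compute_map(sbp, dbp, expected):
    assert ev.compute_map(sbp, dbp) == pytest.approx(expected)


def test_compute_map_rejects_inverted_pressures():
    with pytest.raises(ValueError):
        ev.compute_map(80.0, 120.0)


def test_beat_pressures_ordering_invariant():
    with pytest.raises(ValueError):
        ev.BeatPressures(sbp=100.0, dbp=80.0, map=120.0)


# --- SBP/DBP extraction ---------------------------------------------------

def test_extract_on_pure_cosine_recovers_exact_extrema():
    fs = 125.0
    t = np.arange(1000) / fs
    x = 100.0 + 20.0 * np.cos(2 * np.pi * 1.2 * t)  # 72 bpm
    bp = ev.extract_sbp_dbp(x, fs)
    assert bp.sbp == pytest.approx(120.0, abs=0.05)
    assert bp.dbp == pytest.approx(80.0, abs=0.05)


def test_extract_on_noiseless_simulated_segment():
    pair = simulate_pair(SimParams(noise_sd=0.0, drift_amp=0.0, seed=4))
    bp = ev.extract_sbp_dbp(pair.abp, pair.fs_hz)
    assert bp.sbp == pytest.approx(120.0, abs=1.0)
    assert bp.dbp == pytest.approx(80.0, abs=1.0)


def test_extract_flat_segment_raises_no_beats():
    with pytest.raises(ev.NoBeatsError):
        ev.extract_sbp_dbp(np.full(1000, 90.0), 125.0)


def test_extract_rejects_too_short_segment():
    with pytest.raises(ValueError):
        ev.extract_sbp_dbp(np.zeros(100), 125.0)


def test_map_from_peaks_differs_from_trace_mean():
    # asymmetric pulse: [SBP+2*DBP]/3 from beat extrema is not the trace mean
    pair = simulate_pair(SimParams(noise_sd=0.0, drift_amp=0.0, seed=0))
    bp = ev.extract_sbp_dbp(pair.abp, pair.fs_hz)
    assert abs(bp.map - float(np.mean(pair.abp))) > 0.3


# --- Bland-Altman ---------------------------------------------------------

def test_bland_altman_perfect_agreement():
    t = np.linspace(80, 120, 10)
    res = ev.bland_altman(t, t)
    assert res.mu == 0.0 and res.sigma == 0.0
    assert res.loa_low == 0.0 and res.loa_high == 0.0
    assert res.aami_pass


def test_bland_altman_constant_bias_five_fails_aami():
    t = np.linspace(80, 120, 10)
    res = ev.bland_altman(t, t + 5.0)
    assert res.mu == pytest.approx(5.0)
    assert res.sigma == 0.0
    assert not res.aami_pass  # |mu| >= 5


def test_bland_altman_recovers_gaussian_error_moments():
    rng = np.random.default_rng(2024)
    t = rng.uniform(70, 110, size=1000)
    e = t + rng.normal(3.0, 2.0, size=1000)
    res = ev.bland_altman(t, e)
    assert res.mu == pytest.approx(3.0, abs=0.2)
    assert res.sigma == pytest.approx(2.0, abs=0.15)
    assert res.loa_high - res.loa_low == pytest.approx(2 * 1.96 * res.sigma)


def test_bland_altman_validation():
    with pytest.raises(ValueError):
        ev.bland_altman([1.0], [1.0])
    with pytest.raises(ValueError):
        ev.bland_altman([1.0, 2.0], [1.0, 2.0, 3.0])


def test_aami_verdict_on_reported_scale_error():
    # a mean error of 2.95 with SD 19.33 mmHg does not meet AAMI (sigma >= 8)
    rng = np.random.default_rng(0)
    t = rng.uniform(70, 110, size=5000)
    res = ev.bland_altman(t, t + rng.normal(2.95, 19.33, size=5000))
    assert not res.aami_pass


# --- calibration ----------------------------------------------------------

def test_calibration_removes_constant_bias_exactly():
    rng = np.random.default_rng(1)
    true = rng.uniform(80, 110, size=900)
    est = true + 7.5
    cal_est, cal_true, n_cal = ev.calibrate(est, true, cal_duration_s=60.0,
                                            segment_duration_s=10.0)
    assert n_cal == 6
    assert len(cal_est) == 894
    np.testing.assert_array_equal(cal_est, cal_true)  # bias removed exactly


def test_calibration_preserves_error_spread():
    rng = np.random.default_rng(3)
    true = rng.uniform(80, 110, size=200)
    noise = rng.normal(0.0, 2.0, size=200)
    est = true + 4.0 + noise
    cal_est, cal_true, n_cal = ev.calibrate(est, true, 60.0, 10.0)
    before = np.std((est - true)[n_cal:], ddof=1)
    after = np.std(cal_est - cal_true, ddof=1)
    assert after == pytest.approx(before)  # offset shift leaves sigma unchanged


def test_calibration_shrinks_bias_on_zero_mean_noise():
    rng = np.random.default_rng(4)
    true = rng.uniform(80, 110, size=900)
    est = true + rng.normal(0.0, 3.0, size=900)
    cal_est, cal_true, _ = ev.calibrate(est, true, 60.0, 10.0)
    pre = abs(np.mean(est - true))
    post = abs(np.mean(cal_est - cal_true))
    # the calibration offset itself is estimated from 6 segments, so the
    # residual bias is bounded by the offset's own sampling error
    assert post <= pre + 3.0 * 3.0 / np.sqrt(6)


def test_calibration_window_validation():
    with pytest.raises(ValueError):
        ev.calibrate([1.0] * 10, [1.0] * 10, cal_duration_s=5.0, segment_duration_s=10.0)
    with pytest.raises(ValueError):
        ev.calibrate([1.0] * 3, [1.0] * 3, cal_duration_s=60.0, segment_duration_s=10.0)


# --- similarity metrics ---------------------------------------------------

def _dtw_table_oracle(a, b):
    n, m = len(a), len(b)
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = abs(a[i - 1] - b[j - 1]) + min(D[i - 1, j], D[i, j - 1],
                                                     D[i - 1, j - 1])
    return D[n, m]


def test_dtw_trivial_cases():
    x = np.array([0.3, 1.2, -0.5, 0.0])
    assert ev.dtw_distance(x, x) == 0.0
    assert ev.dtw_distance([0.0, 0.0], [1.0, 1.0]) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        ev.dtw_distance([], [1.0])


def test_dtw_matches_full_table_oracle_and_symmetry(rng):
    for _ in range(40):
        a = rng.normal(size=rng.integers(2, 31))
        b = rng.normal(size=rng.integers(2, 31))
        d = ev.dtw_distance(a, b)
        assert d == pytest.approx(_dtw_table_oracle(a, b), rel=1e-12)
        assert d == pytest.approx(ev.dtw_distance(b, a), rel=1e-12)


def test_rmse_examples_and_oracle(rng):
    a = rng.normal(size=30)
    assert ev.rmse(a, a) == 0.0
    assert ev.rmse(a, a + 0.7) == pytest.approx(0.7)
    b = rng.normal(size=30)
    loop = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / 30)
    assert ev.rmse(a, b) == pytest.approx(loop, abs=1e-10)
    with pytest.raises(ValueError):
        ev.rmse(a, b[:10])


def test_pearson_examples_and_oracle(rng):
    x = rng.normal(size=40)
    assert ev.pearson_cc(x, x) == pytest.approx(1.0)
    assert ev.pearson_cc(x, -x) == pytest.approx(-1.0)
    y = rng.normal(size=40)
    mx, my = x.mean(), y.mean()
    loop = (sum((a - mx) * (b - my) for a, b in zip(x, y))
            / np.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)))
    assert ev.pearson_cc(x, y) == pytest.approx(loop, abs=1e-10)
    with pytest.raises(ValueError):
        ev.pearson_cc(x, np.full(40, 2.0))


# --- dataset evaluation ---------------------------------------------------

def _fast_segments(n, seed=0, seg_s=10.0, fs=25.0):
    """Small 10-s segments for quick dataset-level tests."""
    params = SimParams(hr_bpm=72.0, fs_hz=fs, seg_len_samples=int(seg_s * fs),
                       noise_sd=0.0, drift_amp=0.0)
    segs = []
    rng = np.random.default_rng(seed)
    for k in range(n):
        p = dataclasses.replace(params, seed=int(rng.integers(2 ** 31)),
                                sbp_mmhg=120.0 + rng.normal(0, 5),
                                dbp_mmhg=80.0 + rng.normal(0, 3))
        segs.append(simulate_pair(p).abp)
    return segs


def test_evaluate_dataset_identical_signals():
    segs = _fast_segments(8)
    report = ev.evaluate_dataset(segs, [s.copy() for s in segs], fs_hz=25.0)
    assert report.similarity.dtw == 0.0
    assert report.similarity.rmse == 0.0
    assert report.similarity.pcc == pytest.approx(1.0)
    assert report.bland_altman.mu == 0.0
    assert report.n_failed == 0


def test_evaluate_dataset_metrics_are_segment_means(rng):
    real = _fast_segments(6, seed=1)
    gen = [s + rng.normal(0, 2.0, size=len(s)) for s in real]
    report = ev.evaluate_dataset(real, gen, fs_hz=25.0)
    ok = report.per_segment[report.per_segment["ok"]]
    assert report.similarity.rmse == pytest.approx(float(ok["rmse"].mean()))
    assert report.similarity.pcc == pytest.approx(float(ok["pcc"].mean()))
    assert report.similarity.dtw == pytest.approx(float(ok["dtw"].mean()))


def test_evaluate_dataset_900_segments_with_1min_calibration():
    real = _fast_segments(900, seed=2)
    gen = [s + 5.0 for s in real]
    report = ev.evaluate_dataset(real, gen, fs_hz=25.0, cal_duration_s=60.0)
    assert report.n_segments == 900
    assert report.n_evaluated == 894  # 6 ten-second segments consumed
    assert report.bland_altman_calibrated.mu == pytest.approx(0.0, abs=1e-9)
    assert report.bland_altman.mu == pytest.approx(5.0, abs=0.5)


def test_evaluate_dataset_counts_failed_segments():
    real = _fast_segments(4)
    gen = [s.copy() for s in real]
    gen[2] = np.full_like(gen[2], 90.0)  # flat-line generated segment
    report = ev.evaluate_dataset(real, gen, fs_hz=25.0)
    assert report.n_failed == 1
    assert report.n_evaluated == 3


def test_report_serialization(tmp_path):
    real = _fast_segments(8)
    report = ev.evaluate_dataset(real, [s + 2.0 for s in real], fs_hz=25.0)
    report.save(tmp_path)
    assert (tmp_path / "per_segment.csv").exists()
    summary = (tmp_path / "summary.tsv").read_text()
    assert "mu_mmhg" in summary and "pcc" in summary
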