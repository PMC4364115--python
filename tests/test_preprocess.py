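"""Filtering, segmentation, epoch normalization and outlier replacement."""
import numpy as np
import pytest

from graspkin import preprocess as pp
from graspkin.datatypes import SegmentationError, SegmentationParams, SegmentationResult

from conftest import make_matrix, make_trial

PARAMS = SegmentationParams()


# ---------------------------------------------------------------- filtering

def test_lowpass_preserves_constant():
    x = np.full((200, 3), 7.5)
    assert np.allclose(pp.lowpass_filter(x, 6.0, 100.0), x)


def test_lowpass_attenuates_high_frequency():
    # dual-pass 2nd-order Butterworth: |H(30 Hz)| = 1/(1+(30/6)^4) ~ 0.0016
    t = np.arange(500) / 100.0
    x = np.sin(2 * np.pi * 30.0 * t)
    y = pp.lowpass_filter(x, 6.0, 100.0)
    assert np.max(np.abs(y[50:-50])) < 0.01


def test_lowpass_preserves_linear_ramp():
    x = np.linspace(0.0, 50.0, 400)
    y = pp.lowpass_filter(x, 6.0, 100.0)
    assert np.allclose(y[50:-50], x[50:-50], atol=1e-6)


def test_lowpass_rejects_short_series_and_low_rate():
    with pytest.raises(ValueError, match="too short"):
        pp.lowpass_filter(np.zeros(5), 6.0, 100.0)
    with pytest.raises(ValueError, match="exceed twice"):
        pp.lowpass_filter(np.zeros(100), 60.0, 100.0)


# --------------------------------------------------------------- wrist speed

def test_wrist_speed_constant_velocity():
    # rad advances (3, 4, 0) mm per 10 ms frame -> 500 mm/s everywhere
    steps = np.arange(50)[:, None] * np.array([3.0, 4.0, 0.0])
    trial = make_trial({"rad": steps})
    assert np.allclose(pp.wrist_speed(trial), 500.0)


def test_wrist_speed_stationary():
    trial = make_trial({"rad": np.tile([10.0, 20.0, 30.0], (30, 1))})
    assert np.allclose(pp.wrist_speed(trial), 0.0)


def test_wrist_speed_matches_bruteforce_finite_differences():
    rng = np.random.default_rng(0)
    pos = np.cumsum(rng.normal(0, 2, (80, 3)), axis=0)
    trial = make_trial({"rad": pos})
    dt = 0.01
    expected = np.empty(80)
    for i in range(80):
        if i == 0:
            v = (pos[1] - pos[0]) / dt
        elif i == 79:
            v = (pos[-1] - pos[-2]) / dt
        else:
            v = (pos[i + 1] - pos[i - 1]) / (2 * dt)
        expected[i] = np.linalg.norm(v)
    assert np.allclose(pp.wrist_speed(trial), expected)


def test_wrist_speed_needs_three_samples():
    with pytest.raises(ValueError):
        pp.wrist_speed(make_trial({"rad": np.zeros((2, 3))}))


# -------------------------------------------------------------- segmentation

def _times(n):
    return np.arange(n) * 10.0


def _bruteforce_onset(speed, thr=20.0, w=10):
    for i in range(len(speed) - w):
        if np.all(speed[i:i + w + 1] > thr):
            return i
    return None


def _bruteforce_offset(speed, onset_idx, thr=20.0):
    peak = onset_idx + int(np.argmax(speed[onset_idx:]))
    for j in range(peak + 1, len(speed)):
        if speed[j] < thr:
            return j
    return len(speed) - 1


def test_onset_simple_sustained_crossing():
    speed = np.r_[np.zeros(50), np.full(50, 30.0)]
    assert pp.detect_reach_onset(speed, _times(100), PARAMS) == 500.0


def test_onset_ignores_transient_excursion():
    # 50 ms above threshold, silence, then a sustained crossing
    speed = np.zeros(100)
    speed[10:15] = 30.0
    speed[30:] = 30.0
    assert pp.detect_reach_onset(speed, _times(100), PARAMS) == 300.0


def test_onset_no_movement_raises():
    with pytest.raises(SegmentationError, match="no movement"):
        pp.detect_reach_onset(np.full(100, 5.0), _times(100), PARAMS)


def test_offset_simple_drop():
    speed = np.r_[np.full(150, 30.0), np.zeros(20)]
    assert pp.detect_reach_offset(speed, _times(170), 0.0, PARAMS) == 1500.0


def test_offset_ignores_dip_before_peak():
    # below-threshold dip before the global speed peak must not end the reach
    speed = np.r_[np.full(30, 40.0), np.full(10, 5.0), np.full(40, 100.0),
                  np.zeros(20)]
    offset = pp.detect_reach_offset(speed, _times(100), 0.0, PARAMS)
    assert offset == 800.0  # first drop after the peak, not the dip at 300 ms


def test_offset_never_drops_warns_and_returns_last():
    speed = np.full(100, 30.0)
    with pytest.warns(UserWarning, match="never dropped"):
        assert pp.detect_reach_offset(speed, _times(100), 0.0, PARAMS) == 990.0


def test_segmentation_matches_bruteforce_on_random_traces():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = 120
        speed = np.abs(rng.normal(15, 15, n))
        speed[rng.integers(20, 60):rng.integers(60, 110)] += rng.uniform(0, 40)
        t = _times(n)
        i = _bruteforce_onset(speed)
        if i is None:
            with pytest.raises(SegmentationError):
                pp.detect_reach_onset(speed, t, PARAMS)
            continue
        assert pp.detect_reach_onset(speed, t, PARAMS) == t[i]
        j = _bruteforce_offset(speed, i)
        with np.errstate(all="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assert pp.detect_reach_offset(speed, t, t[i], PARAMS) == t[j]


def test_segmentation_idempotent_on_its_own_window():
    # re-running detection on the segmented window reproduces the bounds
    t = _times(200)
    tau = np.clip((t - 300) / 1200, 0, 1)
    speed = 800 * (tau * (1 - tau)) ** 2 * 16
    seg = pp.segment_trial(speed, t, PARAMS)
    sel = (t >= seg.onset_time) & (t <= seg.offset_time)
    seg2 = pp.segment_trial(speed[sel], t[sel], PARAMS)
    assert seg2.onset_time == seg.onset_time
    assert seg2.offset_time == seg.offset_time


# -------------------------------------------------------- epoch normalization

def test_epochs_affine_series_exact():
    t = np.arange(0.0, 1001.0, 10.0)
    seg = SegmentationResult(0.0, 1000.0)
    out = pp.normalize_to_epochs(t, t.copy(), seg)
    assert np.allclose(out, np.arange(100.0, 1001.0, 100.0))


def test_epochs_constant_series():
    t = np.arange(0.0, 1001.0, 10.0)
    out = pp.normalize_to_epochs(t, np.full_like(t, 3.3), SegmentationResult(0.0, 1000.0))
    assert np.allclose(out, 3.3)


def test_epochs_match_bruteforce_interpolation():
    rng = np.random.default_rng(7)
    t = np.arange(0.0, 1501.0, 10.0)
    v = rng.normal(size=len(t))
    seg = SegmentationResult(130.0, 1260.0)
    out = pp.normalize_to_epochs(t, v, seg)
    for k, p in enumerate(range(10, 101, 10)):
        target = seg.onset_time + p / 100.0 * seg.movement_duration
        i = int(np.searchsorted(t, target, side="right")) - 1
        if t[i] == target:
            expected = v[i]
        else:
            w = (target - t[i]) / (t[i + 1] - t[i])
            expected = (1 - w) * v[i] + w * v[i + 1]
        assert out[k] == pytest.approx(expected, abs=1e-12)


def test_epochs_outside_support_raises():
    t = np.arange(0.0, 500.0, 10.0)
    with pytest.raises(ValueError, match="outside"):
        pp.normalize_to_epochs(t, t.copy(), SegmentationResult(100.0, 800.0))


def test_epochs_nearest_mode():
    t = np.arange(0.0, 1001.0, 10.0)
    out = pp.normalize_to_epochs(t, t.copy(), SegmentationResult(5.0, 995.0),
                                 interpolation="nearest")
    assert np.all(out % 10 == 0)  # snapped to sample times


# ----------------------------------------------------------------- outliers

def _clean_cell_matrix(n_trials=10):
    """One participant/size cell: all features 10.0 everywhere."""
    return make_matrix(np.full((n_trials, 10, 12), 10.0))


def test_participant_outlier_replaced_by_neighbour_interpolation():
    m = _clean_cell_matrix()
    m.values[0, 3, 0] = 80.0  # mean 17, SD 22.14 -> 2.85 SD deviation
    out, report = pp.replace_participant_outliers(m)
    assert out.values[0, 3, 0] == pytest.approx(10.0)
    assert report.n_replaced == 1
    assert report.replaced_fraction == pytest.approx(1 / m.values.size)
    # everything else untouched
    mask = np.ones_like(m.values, bool)
    mask[0, 3, 0] = False
    assert np.array_equal(out.values[mask], m.values[mask])


def test_participant_outlier_endpoint_extrapolation():
    m = _clean_cell_matrix()
    ramp = np.arange(10.0, 30.0, 2.0)         # 10, 12, ..., 28
    m.values[:, :, 0] = ramp[None, :]
    m.values[0, 0, 0] = 100.0                 # lone outlier at the first epoch
    out, _ = pp.replace_participant_outliers(m)
    # linear extrapolation from epochs 1 and 2 (12, 14) -> 10
    assert out.values[0, 0, 0] == pytest.approx(10.0)


def test_participant_outlier_fully_masked_trial_flagged():
    m = _clean_cell_matrix()
    m.values[0, :, 0] = 80.0
    out, report = pp.replace_participant_outliers(m)
    assert ("t0", "wrist_velocity") in report.flagged_trials
    assert np.allclose(out.values[0, :, 0], 17.0)  # cell mean profile


def test_participant_outliers_noop_without_outliers():
    rng = np.random.default_rng(1)
    m = make_matrix(10.0 + 0.01 * rng.standard_normal((8, 10, 12)))
    # tight cloud: no value beyond 2 SD gets masked only if it exists;
    # compare to a manual mask
    out, report = pp.replace_participant_outliers(m, k_sd=10.0)
    assert report.n_replaced == 0
    assert np.array_equal(out.values, m.values)


def test_participant_outliers_requires_three_trials_per_cell():
    m = make_matrix(np.zeros((2, 10, 12)))
    with pytest.raises(ValueError, match=">= 3 trials"):
        pp.replace_participant_outliers(m)


def test_group_outlier_replaced_within_one_sd_band():
    m = make_matrix(np.zeros((10, 10, 12)))
    m.values[9, 0, 0] = 10.0  # mean 1, SD sqrt(10): deviation 2.85 SD
    out, report = pp.replace_group_outliers(m, rng=0)
    v = out.values[9, 0, 0]
    assert 1.0 <= v <= 1.0 + np.sqrt(10.0)
    assert report.n_replaced == 1
    # deterministic under the seed
    out2, _ = pp.replace_group_outliers(m, rng=0)
    assert np.array_equal(out.values, out2.values)


def test_group_outlier_low_side_band():
    m = make_matrix(np.zeros((10, 10, 12)))
    m.values[:, 0, 0] = [5, 5, 5, 5, 5, 5, 5, 5, 5, -5]
    mu, sd = np.mean(m.values[:, 0, 0]), np.std(m.values[:, 0, 0], ddof=1)
    out, _ = pp.replace_group_outliers(m, rng=1)
    v = out.values[9, 0, 0]
    assert mu - sd <= v <= mu  # replacement lies on the outlier's side


def test_group_outliers_zero_variance_untouched():
    m = make_matrix(np.full((10, 10, 12), 4.0))
    out, report = pp.replace_group_outliers(m, rng=0)
    assert report.n_replaced == 0
    assert np.array_equal(out.values, m.values)
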