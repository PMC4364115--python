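"""Marker preprocessing: low-pass filtering, reach segmentation from wrist
speed, time normalization to ten epochs, and two-level outlier replacement.

Reach onset is the first sample at which the wrist speed exceeds the
threshold (20 mm/s by default) and stays above it for longer than the
persistence window (100 ms); offset is the first drop below the threshold
after the post-onset speed peak.  Constraining the offset to follow the peak
ignores transient early dips in noisy speed traces.

Outlier replacement happens on the epoch-level feature matrix in two passes:
first within each participant-by-object cell (masked values refilled by
linear interpolation along the epoch axis), then at group level (masked
values replaced by a seeded uniform draw between the group mean and one SD
on the outlier's side of the mean).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .datatypes import (
    EpochFeatureMatrix,
    SegmentationError,
    SegmentationParams,
    SegmentationResult,
    TrialRecording,
)
from .io import read_trial_table  # re-exported: parsing lives in graspkin.io

__all__ = [
    "read_trial_table", "lowpass_filter", "wrist_speed", "detect_reach_onset",
    "detect_reach_offset", "segment_trial", "normalize_to_epochs",
    "replace_participant_outliers", "replace_group_outliers", "OutlierReport",
]


def lowpass_filter(series: np.ndarray, cutoff: float, rate: float,
                   order: int = 2) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass, applied per column.

    With ``order=2`` the effective magnitude response is
    ``1 / (1 + (f/fc)^4)`` — the movement-science standard dual-pass filter.
    Length is preserved; raises for series too short to filter stably.
    """
    series = np.asarray(series, dtype=float)
    if rate <= 2 * cutoff:
        raise ValueError(f"sampling rate {rate} Hz must exceed twice the cutoff {cutoff} Hz")
    b, a = signal.butter(order, cutoff, btype="low", fs=rate)
    padlen = 3 * max(len(a), len(b))
    n = series.shape[0]
    if n <= padlen:
        raise ValueError(
            f"series of length {n} is too short for stable filtering (needs > {padlen})")
    return signal.filtfilt(b, a, series, axis=0)


def wrist_speed(trial: TrialRecording, *, positions: np.ndarray | None = None) -> np.ndarray:
    """Speed (mm/s) of the wrist marker: norm of the central-difference
    derivative of the ``rad`` position; one-sided differences at the ends.

    ``positions`` overrides the raw marker track (e.g. to pass a filtered
    version).
    """
    pos = trial.marker("rad") if positions is None else np.asarray(positions, float)
    if pos.shape[0] < 3:
        raise ValueError("need at least 3 samples to differentiate the wrist track")
    t_s = np.asarray(trial.time_ms, dtype=float) / 1000.0
    vel = np.gradient(pos, t_s, axis=0)
    return np.linalg.norm(vel, axis=1)


def _persistence_samples(params: SegmentationParams, rate: float) -> int:
    return int(round(params.min_above_duration / 1000.0 * rate))


def detect_reach_onset(speed: np.ndarray, time_ms: np.ndarray,
                       params: SegmentationParams = SegmentationParams()) -> float:
    """Time (ms) of the first sustained crossing above the speed threshold.

    A sample qualifies if it and every sample within the persistence window
    after it exceed the threshold.  Raises :class:`SegmentationError` when no
    sample qualifies ("no movement detected").
    """
    speed = np.asarray(speed, float)
    time_ms = np.asarray(time_ms, float)
    if len(speed) != len(time_ms):
        raise ValueError("speed and time vectors must have equal length")
    rate = 1000.0 / float(np.median(np.diff(time_ms)))
    w = _persistence_samples(params, rate)
    above = speed > params.speed_threshold
    # candidate i must have above[i : i + w + 1] all True (window spans min_above_duration)
    for i in range(len(speed) - w):
        if above[i] and above[i:i + w + 1].all():
            return float(time_ms[i])
    raise SegmentationError("no movement detected: wrist speed never crossed "
                            f"{params.speed_threshold} mm/s for more than "
                            f"{params.min_above_duration} ms")


def detect_reach_offset(speed: np.ndarray, time_ms: np.ndarray, onset_time: float,
                        params: SegmentationParams = SegmentationParams()) -> float:
    """Time (ms) of the first drop below the threshold after the post-onset
    speed peak; falls back to the last sample (with a warning) if the speed
    never drops."""
    speed = np.asarray(speed, float)
    time_ms = np.asarray(time_ms, float)
    onset_idx = int(np.searchsorted(time_ms, onset_time))
    if onset_idx >= len(speed):
        raise SegmentationError("onset_time lies beyond the end of the series")
    peak_idx = onset_idx + int(np.argmax(speed[onset_idx:]))
    below = np.nonzero(speed[peak_idx + 1:] < params.speed_threshold)[0]
    if len(below) == 0:
        warnings.warn("wrist speed never dropped below threshold after the peak; "
                      "using the last sample as reach offset", stacklevel=2)
        return float(time_ms[-1])
    return float(time_ms[peak_idx + 1 + below[0]])


def segment_trial(speed: np.ndarray, time_ms: np.ndarray,
                  params: SegmentationParams = SegmentationParams()) -> SegmentationResult:
    onset = detect_reach_onset(speed, time_ms, params)
    offset = detect_reach_offset(speed, time_ms, onset, params)
    if not offset > onset:
        raise SegmentationError("reach offset does not follow onset")
    return SegmentationResult(onset_time=onset, offset_time=offset)


def normalize_to_epochs(time_ms: np.ndarray, values: np.ndarray,
                        seg: SegmentationResult,
                        epochs_pct: np.ndarray | None = None,
                        interpolation: str = "linear") -> np.ndarray:
    """Sample a time series at 10%..100% of movement duration.

    Values are linearly interpolated between neighbouring samples
    (``interpolation='nearest'`` snaps to the closest sample instead).
    ``values`` may be 1-D or (n, k); the epoch axis comes first in the output.
    """
    time_ms = np.asarray(time_ms, float)
    values = np.asarray(values, float)
    if epochs_pct is None:
        epochs_pct = np.arange(10, 101, 10)
    targets = seg.onset_time + epochs_pct / 100.0 * seg.movement_duration
    if targets[0] < time_ms[0] - 1e-9 or targets[-1] > time_ms[-1] + 1e-9:
        raise ValueError("requested epoch times fall outside the series support")
    if interpolation == "nearest":
        idx = np.abs(time_ms[None, :] - targets[:, None]).argmin(axis=1)
        return values[idx]
    if interpolation != "linear":
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if values.ndim == 1:
        return np.interp(targets, time_ms, values)
    return np.stack([np.interp(targets, time_ms, values[:, k])
                     for k in range(values.shape[1])], axis=1)


# ---------------------------------------------------------------------------
# outlier replacement on the epoch-level feature matrix
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    """Bookkeeping for one replacement pass."""

    n_replaced: int
    n_total: int
    flagged_trials: list[tuple[str, str]]  # (trial_id, feature) fully-masked cases

    @property
    def replaced_fraction(self) -> float:
        return self.n_replaced / self.n_total if self.n_total else 0.0


def _fill_masked_epochs(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Refill masked entries of a 10-vector by linear interpolation along the
    epoch axis; masked endpoints are linearly extrapolated from the two
    nearest unmasked epochs."""
    good = np.nonzero(~mask)[0]
    out = values.copy()
    bad = np.nonzero(mask)[0]
    if len(good) == 1:
        out[bad] = values[good[0]]
        return out
    for i in bad:
        if i < good[0]:      # extrapolate from the two nearest good epochs
            a, b = good[0], good[1]
        elif i > good[-1]:
            a, b = good[-2], good[-1]
        else:
            a = good[good < i][-1]
            b = good[good > i][0]
        slope = (values[b] - values[a]) / (b - a)
        out[i] = values[a] + slope * (i - a)
    return out


def replace_participant_outliers(matrix: EpochFeatureMatrix, k_sd: float = 2.0,
                                 ) -> tuple[EpochFeatureMatrix, OutlierReport]:
    """Mask values deviating more than ``k_sd`` SD from their
    participant-by-object cell mean (per feature, per epoch) and refill them
    by linear interpolation/extrapolation along the epoch axis within the
    trial.  A trial with all ten epochs masked for a feature is flagged and
    set to the cell mean profile."""
    out = matrix.copy()
    v = out.values
    n, n_e, n_f = v.shape
    mask = np.zeros_like(v, dtype=bool)
    cell_means = np.empty_like(v)
    for pid in np.unique(out.participant_ids):
        for size in np.unique(out.labels):
            rows = np.nonzero((out.participant_ids == pid) & (out.labels == size))[0]
            if len(rows) < 3:
                raise ValueError(
                    f"participant {pid}, object {size}: need >= 3 trials per cell, "
                    f"got {len(rows)}")
            cell = v[rows]                            # (m, 10, 12)
            mu = cell.mean(axis=0)
            sd = cell.std(axis=0, ddof=1)
            with np.errstate(invalid="ignore"):
                z = np.abs(cell - mu) > k_sd * sd
            z &= sd > 0
            mask[rows] = z
            cell_means[rows] = mu[None]
    flagged: list[tuple[str, str]] = []
    for i in range(n):
        for f in range(n_f):
            m = mask[i, :, f]
            if not m.any():
                continue
            if m.all():
                v[i, :, f] = cell_means[i, :, f]
                flagged.append((str(out.trial_ids[i]), out.feature_names[f]))
            else:
                v[i, :, f] = _fill_masked_epochs(matrix.values[i, :, f], m)
    report = OutlierReport(n_replaced=int(mask.sum()), n_total=int(mask.size),
                           flagged_trials=flagged)
    return out, report


def replace_group_outliers(matrix: EpochFeatureMatrix, k_sd: float = 2.0,
                           rng: np.random.Generator | int | None = 0,
                           ) -> tuple[EpochFeatureMatrix, OutlierReport]:
    """Replace values deviating more than ``k_sd`` SD from the pooled group
    mean (per object, feature and epoch) by a uniform random value between
    the group mean and one SD on the outlier's side of the mean."""
    rng = np.random.default_rng(rng)
    out = matrix.copy()
    v = out.values
    n_replaced = 0
    for size in np.unique(out.labels):
        rows = np.nonzero(out.labels == size)[0]
        if len(rows) < 3:
            raise ValueError(f"object {size}: need >= 3 trials pooled at group level")
        grp = v[rows]
        mu = grp.mean(axis=0)
        sd = grp.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore"):
            bad = (np.abs(grp - mu) > k_sd * sd) & (sd > 0)
        idx = np.argwhere(bad)
        for (i, e, f) in idx:
            side = np.sign(grp[i, e, f] - mu[e, f])
            lo, hi = sorted((mu[e, f], mu[e, f] + side * sd[e, f]))
            v[rows[i], e, f] = rng.uniform(lo, hi)
        n_replaced += len(idx)
    report = OutlierReport(n_replaced=n_replaced, n_total=int(v.size), flagged_trials=[])
    return out, report
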