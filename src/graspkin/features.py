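"""Hand-centered local frame and the twelve time-resolved kinematic features.

The hand frame has its origin at the index metacarpal marker (ind1).  The
metacarpal plane is spanned by the wrist (rad) and little-finger metacarpal
(lit1) markers: x points ulnarly (toward lit1), z is the dorsal normal of the
plane, and y = z x x points distally.  The frame is rebuilt at every sample
because the hand rotates during transport; digit coordinates and the
finger-plane normal are therefore invariant under rigid motions of the whole
trial.

The finger plane passes through the thumb trapezium (thu0), the index tip
(ind3) and the thumb tip (thu4); its unit normal, expressed in the hand
frame, encodes thumb/index abduction-adduction independently of wrist
rotation.  The normal's sign is fixed dorsal-positive at the first sample and
by continuity (maximal dot product with the previous sample) afterwards.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import (
    EPOCH_PERCENTS,
    FEATURE_NAMES,
    DegenerateGeometryError,
    EpochFeatureMatrix,
    SegmentationError,
    SegmentationParams,
    TrialRecording,
)
from . import preprocess

logger = logging.getLogger(__name__)

_COLLINEAR_TOL = 1e-12


@dataclass(frozen=True)
class LocalFrame:
    """Orthonormal right-handed hand frame: origin at ind1, axes in global
    coordinates (x ulnar, y distal, z dorsal)."""

    origin: np.ndarray          # (3,)
    axes: np.ndarray            # (3, 3), rows = x_hat, y_hat, z_hat

    @property
    def x_hat(self) -> np.ndarray:
        return self.axes[0]

    @property
    def y_hat(self) -> np.ndarray:
        return self.axes[1]

    @property
    def z_hat(self) -> np.ndarray:
        return self.axes[2]


def build_local_frame(rad: np.ndarray, ind1: np.ndarray, lit1: np.ndarray,
                      handedness: str = "right") -> LocalFrame:
    """Construct the hand frame from the three metacarpal-plane markers.

    ``handedness='left'`` flips the cross-product order so that z remains
    dorsal for a left hand.
    """
    rad, ind1, lit1 = (np.asarray(p, float) for p in (rad, ind1, lit1))
    u = lit1 - ind1
    v = rad - ind1
    nu = np.linalg.norm(u)
    scale = max(nu, np.linalg.norm(v), 1.0)
    normal = np.cross(v, u) if handedness == "right" else np.cross(u, v)
    nn = np.linalg.norm(normal)
    if nu < _COLLINEAR_TOL * scale or nn < _COLLINEAR_TOL * scale**2:
        raise DegenerateGeometryError(
            "rad/ind1/lit1 markers are collinear or coincident; hand frame undefined")
    x_hat = u / nu
    z_hat = normal / nn
    y_hat = np.cross(z_hat, x_hat)
    return LocalFrame(origin=ind1, axes=np.stack([x_hat, y_hat, z_hat]))


def to_local(point: np.ndarray, frame: LocalFrame) -> np.ndarray:
    """Coordinates of ``point`` in the hand frame (projections of
    point - origin onto the axes).  Works on (3,) or (n, 3) input."""
    p = np.asarray(point, float)
    return (p - frame.origin) @ frame.axes.T


def from_local(coords: np.ndarray, frame: LocalFrame) -> np.ndarray:
    """Inverse of :func:`to_local`."""
    return np.asarray(coords, float) @ frame.axes + frame.origin


def grip_aperture(thu4: np.ndarray, ind3: np.ndarray) -> float | np.ndarray:
    """Euclidean thumb-tip to index-tip distance (mm); symmetric in its
    arguments.  Accepts (3,) points or (n, 3) tracks."""
    d = np.asarray(thu4, float) - np.asarray(ind3, float)
    return np.linalg.norm(d, axis=-1)


def wrist_height(rad: np.ndarray) -> float | np.ndarray:
    """Global z-component of the wrist marker (mm); the trial-table dialect
    requires z to be the vertical axis."""
    return np.asarray(rad, float)[..., 2]


def finger_plane_normal(thu0: np.ndarray, ind3: np.ndarray, thu4: np.ndarray,
                        frame: LocalFrame,
                        previous_normal: np.ndarray | None = None) -> np.ndarray:
    """Unit normal of the plane through thu0, ind3 and thu4, expressed in the
    hand frame.

    Sign convention: maximal dot product with ``previous_normal`` when given;
    otherwise the thu0 -> ind3 -> thu4 triangle winding, which is anatomically
    fixed (thumb and index cannot pass through each other) and dorsal-positive
    in the canonical grasp posture.  A winding-based orientation stays
    well-conditioned when the normal is nearly orthogonal to the dorsal axis,
    where a z-sign rule would flip erratically across trials.
    """
    thu0, ind3, thu4 = (np.asarray(p, float) for p in (thu0, ind3, thu4))
    v1 = ind3 - thu0
    v2 = thu4 - thu0
    n = np.cross(v1, v2)
    norm = np.linalg.norm(n)
    scale = max(np.linalg.norm(v1), np.linalg.norm(v2), 1.0)
    if norm < _COLLINEAR_TOL * scale**2:
        raise DegenerateGeometryError(
            "thu0/ind3/thu4 are collinear; finger plane undefined")
    n_local = (n / norm) @ frame.axes.T
    if previous_normal is not None and np.dot(n_local, previous_normal) < 0:
        n_local = -n_local
    return n_local


def trial_feature_series(trial: TrialRecording,
                         params: SegmentationParams = SegmentationParams(),
                         ) -> tuple[np.ndarray, np.ndarray, "preprocess.SegmentationResult"]:
    """Per-sample 12-feature series for one trial, plus its segmentation.

    Markers are low-pass filtered, the reach is segmented on wrist speed, and
    every feature is evaluated at every retained sample.  Returns
    ``(time_ms, series (n, 12), segmentation)``.
    """
    filtered = {m: preprocess.lowpass_filter(xyz, params.filter_cutoff,
                                             trial.sampling_rate,
                                             order=params.filter_order)
                for m, xyz in trial.positions.items()}
    speed = preprocess.wrist_speed(trial, positions=filtered["rad"])
    seg = preprocess.segment_trial(speed, trial.time_ms, params)
    n = trial.n_samples
    series = np.empty((n, 12))
    series[:, 0] = speed
    series[:, 1] = wrist_height(filtered["rad"])
    series[:, 2] = grip_aperture(filtered["thu4"], filtered["ind3"])
    prev_normal = None
    for i in range(n):
        frame = build_local_frame(filtered["rad"][i], filtered["ind1"][i],
                                  filtered["lit1"][i])
        series[i, 3:6] = to_local(filtered["ind3"][i], frame)
        series[i, 6:9] = to_local(filtered["thu4"][i], frame)
        normal = finger_plane_normal(filtered["thu0"][i], filtered["ind3"][i],
                                     filtered["thu4"][i], frame, prev_normal)
        series[i, 9:12] = normal
        prev_normal = normal
    return trial.time_ms, series, seg


def extract_feature_matrix(trials: list[TrialRecording],
                           params: SegmentationParams = SegmentationParams(),
                           ) -> EpochFeatureMatrix:
    """Run the full per-trial pipeline (filter, segment, per-sample features,
    epoch normalization) and assemble the trials x 10 x 12 matrix.

    Trials that fail segmentation (e.g. no movement) are dropped with a
    logged reason; an empty result raises :class:`SegmentationError`.
    """
    rows, tids, pids, labels = [], [], [], []
    for trial in trials:
        try:
            time_ms, series, seg = trial_feature_series(trial, params)
        except (SegmentationError, DegenerateGeometryError, ValueError) as exc:
            logger.warning("dropping trial %s: %s", trial.trial_id, exc)
            continue
        epochs = preprocess.normalize_to_epochs(time_ms, series, seg, EPOCH_PERCENTS)
        # interpolation between unit normals shrinks their norm slightly;
        # restore exact unit length per epoch
        fp = epochs[:, 9:12]
        epochs[:, 9:12] = fp / np.linalg.norm(fp, axis=1, keepdims=True)
        rows.append(epochs)
        tids.append(trial.trial_id)
        pids.append(trial.participant_id)
        labels.append(trial.object_size)
    if not rows:
        raise SegmentationError("no trial could be segmented; empty feature matrix")
    return EpochFeatureMatrix(
        values=np.stack(rows),
        trial_ids=np.array(tids),
        participant_ids=np.array(pids),
        labels=np.array(labels),
        feature_names=FEATURE_NAMES,
    )
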