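"""Core containers exchanged between pipeline stages.

The central object is :class:`EpochFeatureMatrix`: one row per trial, ten
time-normalized epochs (10%..100% of movement duration) and twelve named
kinematic features.  Everything downstream (outlier replacement, F-scores,
per-epoch classification) operates on it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The six markers every trial must carry.  rad = radial wrist; ind1/ind3 =
#: index metacarpal joint / index tip; lit1 = little-finger metacarpal joint;
#: thu0/thu4 = thumb trapezium / thumb tip.
REQUIRED_MARKERS: tuple[str, ...] = ("rad", "ind1", "ind3", "lit1", "thu0", "thu4")

#: Canonical order of the twelve kinematic features.
FEATURE_NAMES: tuple[str, ...] = (
    "wrist_velocity",   # mm/s, magnitude of wrist (rad) velocity
    "wrist_height",     # mm, global z of the wrist marker
    "grip_aperture",    # mm, |thu4 - ind3|
    "index_x", "index_y", "index_z",            # mm, index tip in the hand frame
    "thumb_x", "thumb_y", "thumb_z",            # mm, thumb tip in the hand frame
    "fingerplane_x", "fingerplane_y", "fingerplane_z",  # unit normal components
)

#: Epoch grid: percentages of normalized movement duration.
EPOCH_PERCENTS: np.ndarray = np.arange(10, 101, 10)

OBJECT_SIZES: tuple[str, str] = ("small", "large")


class GraspkinError(Exception):
    """Base class for errors raised by this package."""


class TrialParseError(GraspkinError):
    """A trial table failed validation (missing marker, bad timestamps...)."""


class SegmentationError(GraspkinError):
    """Reach onset/offset could not be determined from the wrist speed."""


class DegenerateGeometryError(GraspkinError):
    """Markers are collinear/coincident; a frame or plane is undefined."""


@dataclass
class TrialRecording:
    """One trial's marker trajectories plus metadata.

    ``positions`` maps marker name to an (n_samples, 3) array of x/y/z in mm,
    in the motion-capture (global) frame; ``time_ms`` is the shared, strictly
    increasing time stamp vector sampled at ``sampling_rate``.
    """

    trial_id: str
    participant_id: str
    object_size: str
    sampling_rate: float
    time_ms: np.ndarray
    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.object_size not in OBJECT_SIZES:
            raise ValueError(f"object_size must be one of {OBJECT_SIZES}, got {self.object_size!r}")
        missing = [m for m in REQUIRED_MARKERS if m not in self.positions]
        if missing:
            raise TrialParseError(f"trial {self.trial_id}: missing required marker(s) {missing}")
        n = len(self.time_ms)
        for name, arr in self.positions.items():
            if arr.shape != (n, 3):
                raise TrialParseError(
                    f"trial {self.trial_id}: marker {name} has shape {arr.shape}, expected ({n}, 3)"
                )
        if n >= 2:
            dt = np.diff(np.asarray(self.time_ms, dtype=float))
            if np.any(dt <= 0):
                raise TrialParseError(f"trial {self.trial_id}: non-monotone time stamps")

    @property
    def n_samples(self) -> int:
        return len(self.time_ms)

    def marker(self, name: str) -> np.ndarray:
        return self.positions[name]


@dataclass(frozen=True)
class SegmentationParams:
    """Velocity-threshold segmentation settings.

    onset = first sample above ``speed_threshold`` that stays above it for
    longer than ``min_above_duration``; offset = first drop below the
    threshold after the post-onset speed peak.
    """

    speed_threshold: float = 20.0       # mm/s
    min_above_duration: float = 100.0   # ms
    filter_cutoff: float = 6.0          # Hz, low-pass Butterworth
    filter_order: int = 2               # per pass (applied forward-backward)

    def __post_init__(self) -> None:
        if self.speed_threshold <= 0:
            raise ValueError("speed_threshold must be > 0")
        if self.min_above_duration < 0:
            raise ValueError("min_above_duration must be >= 0")
        if self.filter_cutoff <= 0:
            raise ValueError("filter_cutoff must be > 0")


@dataclass(frozen=True)
class SegmentationResult:
    """Reach onset/offset times (ms) and their difference."""

    onset_time: float
    offset_time: float

    def __post_init__(self) -> None:
        if not self.onset_time < self.offset_time:
            raise ValueError("onset_time must precede offset_time")

    @property
    def movement_duration(self) -> float:
        return self.offset_time - self.onset_time


@dataclass
class EpochFeatureMatrix:
    """trials x 10 epochs x 12 features with labels and participant ids."""

    values: np.ndarray                      # (n_trials, 10, 12)
    trial_ids: np.ndarray                   # (n_trials,) str
    participant_ids: np.ndarray             # (n_trials,) str
    labels: np.ndarray                      # (n_trials,) 'small'|'large'
    feature_names: tuple[str, ...] = FEATURE_NAMES
    epochs: np.ndarray = field(default_factory=lambda: EPOCH_PERCENTS.copy())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 3 or self.values.shape[1] != len(self.epochs) \
                or self.values.shape[2] != len(self.feature_names):
            raise ValueError(
                f"values must have shape (n, {len(self.epochs)}, {len(self.feature_names)}), "
                f"got {self.values.shape}"
            )
        for name, arr in (("trial_ids", self.trial_ids),
                          ("participant_ids", self.participant_ids),
                          ("labels", self.labels)):
            arr = np.asarray(arr)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
        self.trial_ids = np.asarray(self.trial_ids)
        self.participant_ids = np.asarray(self.participant_ids)
        self.labels = np.asarray(self.labels)
        bad = set(np.unique(self.labels)) - set(OBJECT_SIZES)
        if bad:
            raise ValueError(f"unknown object-size labels: {sorted(bad)}")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def feature_index(self, name: str) -> int:
        return self.feature_names.index(name)

    def class_mask(self, label: str) -> np.ndarray:
        return self.labels == label

    def epoch_slice(self, epoch_pct: int) -> np.ndarray:
        """(n_trials, 12) feature slice at one epoch percentage."""
        idx = int(np.nonzero(self.epochs == epoch_pct)[0][0])
        return self.values[:, idx, :]

    def grand_mean(self, feature: str, label: str | None = None) -> float:
        """Average of one feature over epochs and (optionally one class of) trials."""
        f = self.feature_index(feature)
        sel = self.values[:, :, f]
        if label is not None:
            sel = sel[self.class_mask(label)]
        return float(sel.mean())

    def copy(self) -> "EpochFeatureMatrix":
        return EpochFeatureMatrix(
            values=self.values.copy(),
            trial_ids=self.trial_ids.copy(),
            participant_ids=self.participant_ids.copy(),
            labels=self.labels.copy(),
            feature_names=self.feature_names,
            epochs=self.epochs.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: trial_id, participant_id, object_size, epoch_pct, feature, value."""
        n, n_e, n_f = self.values.shape
        return pd.DataFrame({
            "trial_id": np.repeat(self.trial_ids, n_e * n_f),
            "participant_id": np.repeat(self.participant_ids, n_e * n_f),
            "object_size": np.repeat(self.labels, n_e * n_f),
            "epoch_pct": np.tile(np.repeat(self.epochs, n_f), n),
            "feature": np.tile(list(self.feature_names), n * n_e),
            "value": self.values.reshape(-1),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EpochFeatureMatrix":
        required = {"trial_id", "participant_id", "object_size", "epoch_pct", "feature", "value"}
        missing = required - set(df.columns)
        if missing:
            raise TrialParseError(f"feature table missing column(s) {sorted(missing)}")
        epochs = np.sort(df["epoch_pct"].unique())
        features = [f for f in FEATURE_NAMES if f in set(df["feature"])]
        extra = set(df["feature"]) - set(features)
        if extra:
            raise TrialParseError(f"unknown feature name(s) {sorted(extra)}")
        wide = df.pivot_table(index="trial_id", columns=["epoch_pct", "feature"],
                              values="value", sort=False)
        trial_ids = wide.index.to_numpy()
        meta = df.drop_duplicates("trial_id").set_index("trial_id").loc[trial_ids]
        values = np.empty((len(trial_ids), len(epochs), len(features)))
        for i, e in enumerate(epochs):
            for j, f in enumerate(features):
                values[:, i, j] = wide[(e, f)].to_numpy()
        return cls(
            values=values,
            trial_ids=trial_ids.astype(str),
            participant_ids=meta["participant_id"].to_numpy().astype(str),
            labels=meta["object_size"].to_numpy().astype(str),
            feature_names=tuple(features),
            epochs=epochs.astype(int),
        )
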