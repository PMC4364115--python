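"""Readers/writers for the plain-text interchange formats.

Trial tables are UTF-8 TSV with a header and one row per marker per sample:
``trial_id  participant_id  object_size  time_ms  marker  x_mm  y_mm  z_mm``.
Feature matrices travel as long-format TSV (see
:meth:`EpochFeatureMatrix.to_frame`).  Both round-trip losslessly at the
written precision.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    REQUIRED_MARKERS,
    EpochFeatureMatrix,
    TrialParseError,
    TrialRecording,
)

TRIAL_TABLE_COLUMNS = (
    "trial_id", "participant_id", "object_size", "time_ms", "marker",
    "x_mm", "y_mm", "z_mm",
)


def write_trials_tsv(trials: list[TrialRecording], path: str | Path,
                     float_format: str = "%.6f") -> None:
    """Write a dataset of trials as a single trial-table TSV."""
    frames = []
    for tr in trials:
        for marker, xyz in tr.positions.items():
            frames.append(pd.DataFrame({
                "trial_id": tr.trial_id,
                "participant_id": tr.participant_id,
                "object_size": tr.object_size,
                "time_ms": tr.time_ms,
                "marker": marker,
                "x_mm": xyz[:, 0], "y_mm": xyz[:, 1], "z_mm": xyz[:, 2],
            }))
        frames[-1]  # keep marker blocks contiguous per trial
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format=float_format)


def read_trial_table(path: str | Path, sampling_rate: float | None = None,
                     ) -> list[TrialRecording]:
    """Parse a trial-table TSV into :class:`TrialRecording` objects.

    The sampling rate is inferred from the median time step unless given.
    Raises :class:`TrialParseError` naming the offending trial and marker on
    missing markers, missing columns or non-monotone time stamps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    missing_cols = set(TRIAL_TABLE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise TrialParseError(f"trial table missing column(s) {sorted(missing_cols)}")
    trials: list[TrialRecording] = []
    for trial_id, g in df.groupby("trial_id", sort=False):
        markers_present = set(g["marker"])
        for m in REQUIRED_MARKERS:
            if m not in markers_present:
                raise TrialParseError(f"trial {trial_id}: required marker {m!r} not found")
        ref_times = None
        positions: dict[str, np.ndarray] = {}
        for marker, gm in g.groupby("marker", sort=False):
            gm = gm.sort_values("time_ms")
            t = gm["time_ms"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise TrialParseError(
                    f"trial {trial_id}: non-monotone time stamps for marker {marker!r}")
            if ref_times is None:
                ref_times = t
            elif len(t) != len(ref_times) or not np.allclose(t, ref_times):
                raise TrialParseError(
                    f"trial {trial_id}: marker {marker!r} time stamps disagree with "
                    f"the other markers")
            positions[marker] = gm[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        assert ref_times is not None
        rate = sampling_rate
        if rate is None:
            if len(ref_times) < 2:
                raise TrialParseError(f"trial {trial_id}: cannot infer sampling rate "
                                      f"from a single sample")
            rate = 1000.0 / float(np.median(np.diff(ref_times)))
        meta = g.iloc[0]
        trials.append(TrialRecording(
            trial_id=str(trial_id),
            participant_id=str(meta["participant_id"]),
            object_size=str(meta["object_size"]),
            sampling_rate=rate,
            time_ms=ref_times,
            positions=positions,
        ))
    return trials


def write_features_tsv(matrix: EpochFeatureMatrix, path: str | Path,
                       float_format: str = "%.10g") -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False, float_format=float_format)


def read_features_tsv(path: str | Path) -> EpochFeatureMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return EpochFeatureMatrix.from_frame(pd.read_csv(path, sep="\t"))


def write_config_sidecar(config_dict: dict, path: str | Path) -> None:
    """JSON sidecar recording a generator/run configuration next to its data."""
    Path(path).write_text(json.dumps(config_dict, indent=2, sort_keys=True, default=str))


def read_config_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
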