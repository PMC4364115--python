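import numpy as np
import pytest

from graspkin.datatypes import FEATURE_NAMES, REQUIRED_MARKERS, EpochFeatureMatrix, TrialRecording
from graspkin.synthetic import SyntheticConfig


def make_trial(positions: dict[str, np.ndarray], rate: float = 100.0,
               trial_id: str = "t1", size: str = "small",
               participant: str = "p01") -> TrialRecording:
    """TrialRecording factory; markers not supplied are cloned from 'rad'."""
    n = len(next(iter(positions.values())))
    full = {m: positions.get(m, positions["rad"]).copy() for m in REQUIRED_MARKERS}
    return TrialRecording(trial_id=trial_id, participant_id=participant,
                          object_size=size, sampling_rate=rate,
                          time_ms=np.arange(n) * 1000.0 / rate, positions=full)


def make_matrix(values: np.ndarray, labels=None, participants=None) -> EpochFeatureMatrix:
    n = values.shape[0]
    return EpochFeatureMatrix(
        values=values,
        trial_ids=np.array([f"t{i}" for i in range(n)]),
        participant_ids=np.array(participants if participants is not None
                                 else ["p01"] * n),
        labels=np.array(labels if labels is not None else ["small"] * n),
    )


ZERO_SD = {f: 0.0 for f in FEATURE_NAMES}


@pytest.fixture(scope="session")
def tiny_marker_config() -> SyntheticConfig:
    """Low-noise marker-mode configuration used across geometry tests."""
    return SyntheticConfig(seed=3, n_participants=2, n_trials_per_size=3,
                           participant_sd=dict(ZERO_SD), trial_noise_sd=dict(ZERO_SD),
                           marker_noise_sd=0.05)
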