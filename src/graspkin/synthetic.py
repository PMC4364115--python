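"""Synthetic reach-to-grasp datasets with configurable object-size effects.

Two generation modes share one calibrated movement model:

* marker mode (:func:`simulate_trial_markers`, :func:`simulate_dataset`)
  produces full six-marker trajectories at the configured sampling rate —
  a minimum-jerk wrist transport (with a small timing asymmetry so the
  small-object speed exceeds the large-object speed early and the reverse
  late), an arched wrist-height profile, an open-then-close grip-aperture
  profile peaking at 65-70% of movement time, and digit markers placed in
  the hand frame so the local-coordinate and finger-plane features carry
  the configured size effects;
* feature mode (:func:`simulate_feature_dataset`) draws the epoch-level
  feature matrix directly from the same per-epoch mean profiles.

Calibration is closed-loop: the class movement duration, aperture peak and
arch height are solved numerically so that a noiseless trial pushed through
the actual extraction pipeline reproduces the configured per-class grand
means (temporal average over the ten epochs).  The default class means are
the group grand means reported for a 15-participant grapefruit-vs-hazelnut
grasping study; between-participant SDs default to the reported standard
errors times sqrt(15), and within-participant SDs to the same magnitude.

``effect_scale`` multiplies every size effect; at 0 the two classes are
drawn from identical distributions (a null dataset for chance-level
controls).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .datatypes import (
    EPOCH_PERCENTS,
    FEATURE_NAMES,
    OBJECT_SIZES,
    EpochFeatureMatrix,
    SegmentationParams,
    TrialRecording,
)
from . import features as _features
from . import io as _io
from . import preprocess as _preprocess

__all__ = [
    "SyntheticConfig", "simulate_trial_markers", "simulate_dataset",
    "simulate_feature_dataset", "epoch_mean_profiles", "write_dataset",
    "DEFAULT_CLASS_MEANS", "DEFAULT_PARTICIPANT_SD",
]

# Grand means (temporal average over the ten epochs) per class: (small, large).
DEFAULT_CLASS_MEANS: dict[str, tuple[float, float]] = {
    "wrist_velocity": (521.25, 555.74),    # mm/s
    "wrist_height": (68.76, 85.08),        # mm
    "grip_aperture": (42.17, 73.82),       # mm
    "index_x": (-5.99, 3.87),              # mm, hand frame
    "index_y": (54.76, 69.32),
    "index_z": (-73.32, -51.48),
    "thumb_x": (-2.194, -15.17),
    "thumb_y": (14.85, 6.21),
    "thumb_z": (-79.22, -82.40),
    "fingerplane_x": (-0.963, -0.948),     # unit-normal components
    "fingerplane_y": (0.073, 0.153),
    "fingerplane_z": (0.051, 0.190),
}

# Between-participant SDs: reported group standard errors (class-averaged)
# times sqrt(15 participants).
_SQ15 = math.sqrt(15.0)
DEFAULT_PARTICIPANT_SD: dict[str, float] = {
    "wrist_velocity": (16.57 + 13.28) / 2 * _SQ15,
    "wrist_height": 3.53 * _SQ15,
    "grip_aperture": (2.20 + 1.22) / 2 * _SQ15,
    "index_x": (2.32 + 2.17) / 2 * _SQ15,
    "index_y": (2.09 + 1.92) / 2 * _SQ15,
    "index_z": (2.28 + 3.21) / 2 * _SQ15,
    "thumb_x": (1.78 + 1.60) / 2 * _SQ15,
    "thumb_y": (1.71 + 1.94) / 2 * _SQ15,
    "thumb_z": (1.50 + 1.44) / 2 * _SQ15,
    "fingerplane_x": (0.006 + 0.007) / 2 * _SQ15,
    "fingerplane_y": (0.037 + 0.038) / 2 * _SQ15,
    "fingerplane_z": (0.021 + 0.022) / 2 * _SQ15,
}

# --- fixed movement-model geometry (mm, fractions of movement time) --------
_PRE_MS = 300.0          # stationary rest before reach onset
_POST_MS = 250.0         # stationary rest after object contact
_Z_START = 25.0          # wrist-marker height at rest
_RAD_LOCAL = np.array([20.0, -80.0, 0.0])   # wrist marker in the hand frame
_LIT1_OFFSET = 55.0      # hand width: lit1 at (55, 0, 0) in the hand frame
_APERTURE_START = 18.0   # thumb-index marker distance at the start posture
_OBJECT_DIAMETER = {"small": 15.0, "large": 50.0}
_CONTACT_MARGIN = 10.0   # size-neutral contact aperture = mean diameter + margin
_APERTURE_PEAK_LOC = 0.675  # peak of the base open-close profile
# size effects on aperture and wrist height enter as monotonically growing
# difference terms: hands pre-shape from movement onset (a small aperture
# difference exists from the very beginning) and the differences keep
# growing toward contact, while wrist height separates only from mid-reach
_APERTURE_RISE_FLOOR = 0.12   # fraction of the aperture effect present at onset
_APERTURE_RISE_SPAN = 1.0     # movement fraction over which the effect saturates
_WRIST_RISE_SPAN = 1.0
_SPEED_ASYMMETRY = {"small": +0.03, "large": -0.03}  # time-warp coefficient
_PRONATION_RAD = math.radians(20.0)  # hand rotation released over transport
_THU0_ALONG = -55.0      # thumb-trapezium placement in the finger plane
_THU0_ACROSS = -15.0
_DIGIT_SEP_SLOPE = 1.8   # growth rate of digit-posture size effects over time
_MIN_APERTURE = 2.0      # physical floor on thumb-index distance


def _small_large(d: dict[str, tuple[float, float]], feature: str, size: str) -> float:
    return d[feature][OBJECT_SIZES.index(size)]


@dataclass
class SyntheticConfig:
    """Study-design and noise parameters of the synthetic generator."""

    n_participants: int = 15
    n_trials_per_size: int = 30
    sampling_rate: float = 100.0          # Hz
    amplitude: float = 480.0              # mm, transport distance
    mean_duration: float = 1100.0         # ms, initial duration guess
    duration_sd: float = 0.0              # ms, extra trial-level jitter
    class_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MEANS))
    effect_scale: float = 1.0             # 0 = null dataset
    participant_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARTICIPANT_SD))
    trial_noise_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARTICIPANT_SD))
    epoch_noise_frac: float = 0.3         # per-epoch jitter as a fraction of trial SD
    marker_noise_sd: float = 0.3          # mm, i.i.d. marker jitter (marker mode)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_trials_per_size < 1:
            raise ValueError("counts must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.duration_sd < 0 or self.marker_noise_sd < 0 or self.epoch_noise_frac < 0:
            raise ValueError("all SDs must be >= 0")
        for d in (self.participant_sd, self.trial_noise_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("all SDs must be >= 0")
        missing = set(FEATURE_NAMES) - set(self.class_means)
        if missing:
            raise ValueError(f"class_means missing feature(s) {sorted(missing)}")

    def sd_vector(self, which: str) -> np.ndarray:
        d = self.participant_sd if which == "participant" else self.trial_noise_sd
        return np.array([d.get(f, 0.0) for f in FEATURE_NAMES])

    def to_dict(self) -> dict:
        return asdict(self)

    def _calibration_key(self, size: str) -> tuple:
        return (
            size, self.sampling_rate, self.amplitude, self.mean_duration,
            self.effect_scale,
            tuple(sorted((k, tuple(v)) for k, v in self.class_means.items())),
        )


@dataclass
class _ClassModel:
    """Calibrated per-class movement model (all size effects resolved)."""

    size: str
    duration: float                # ms, class movement duration
    kappa: float                   # transport time-warp asymmetry
    aperture_peak: float           # mm, size-neutral base profile
    aperture_end: float            # mm, size-neutral contact aperture
    aperture_start: float          # mm, start-posture aperture
    aperture_peak_loc: float       # fraction of movement time
    aperture_delta: float          # mm, size effect riding on the base profile
    arch_height: float             # mm, size-neutral wrist-arch amplitude
    z_delta: float                 # mm, size effect on late wrist height
    targets: np.ndarray            # (12,) per-feature class grand means at this scale
    t0_hat: np.ndarray             # finger-plane arc center (unit)
    t0_norm: float
    arc_dir: np.ndarray            # in-plane arc direction (unit, horizontal z)
    fp_tilt: np.ndarray            # class tilt added to the arc
    arc_rate: float                # rad per unit tau
    d_hat: np.ndarray              # index-minus-thumb separation direction (unit)
    m_class: np.ndarray            # digit midpoint at this scale (hand frame)
    m_mid: np.ndarray              # size-neutral digit midpoint
    tau_bar: float                 # mean epoch position in movement-time units
    tau_epochs: np.ndarray         # (10,)
    epoch_means: np.ndarray        # (10, 12) noiseless extracted profiles


def _minimum_jerk(u: np.ndarray) -> np.ndarray:
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3 - 2 * x)


def _aperture_profile(tau: np.ndarray, peak: float, end: float,
                      peak_loc: float, start: float = _APERTURE_START) -> np.ndarray:
    rising = tau <= peak_loc
    g = np.where(rising, _smoothstep(tau / peak_loc),
                 1.0 - _smoothstep((tau - peak_loc) / (1.0 - peak_loc)))
    base = np.where(rising, start, end)
    return base + (peak - base) * g


def _aperture_rise(tau: np.ndarray) -> np.ndarray:
    return (_APERTURE_RISE_FLOOR
            + (1.0 - _APERTURE_RISE_FLOOR) * _smoothstep(tau / _APERTURE_RISE_SPAN))


def _wrist_rise(tau: np.ndarray) -> np.ndarray:
    return _smoothstep(tau / _WRIST_RISE_SPAN)


def _rot_y(phi: np.ndarray) -> np.ndarray:
    """(n, 3, 3) rotation matrices about the global y (pronation) axis."""
    c, s = np.cos(phi), np.sin(phi)
    out = np.zeros(phi.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 2] = s
    out[..., 1, 1] = 1.0
    out[..., 2, 0] = -s
    out[..., 2, 2] = c
    return out


def _normalize(v: np.ndarray, axis: int = -1) -> np.ndarray:
    return v / np.linalg.norm(v, axis=axis, keepdims=True)


def _class_targets(config: SyntheticConfig, size: str) -> np.ndarray:
    s = config.effect_scale
    out = np.empty(len(FEATURE_NAMES))
    for i, f in enumerate(FEATURE_NAMES):
        small, large = config.class_means[f]
        mid = 0.5 * (small + large)
        out[i] = mid + s * (_small_large(config.class_means, f, size) - mid)
    return out


def _feature_vec(arr: np.ndarray, name: str) -> float:
    return float(arr[FEATURE_NAMES.index(name)])


def _trial_positions(config: SyntheticConfig, model: _ClassModel,
                     duration_ms: float, effects: np.ndarray,
                     rng: np.random.Generator | None) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Marker trajectories for one trial.

    ``effects`` is a 12-vector of additive feature offsets (participant plus
    trial); the wrist-velocity entry is handled upstream through the trial
    duration.  ``rng=None`` yields the noiseless expected trajectory.
    """
    dt = 1000.0 / config.sampling_rate
    total = _PRE_MS + duration_ms + _POST_MS
    time_ms = np.arange(0.0, total + dt / 2, dt)
    tau = np.clip((time_ms - _PRE_MS) / duration_ms, 0.0, 1.0)

    # wrist transport: warped minimum jerk along y, arched z
    u = tau + model.kappa * tau * (1.0 - tau)
    rad = np.zeros((len(tau), 3))
    rad[:, 1] = config.amplitude * _minimum_jerk(u)
    z_off = _feature_vec(effects, "wrist_height")
    rad[:, 2] = (_Z_START + z_off
                 + model.arch_height * np.sin(np.pi * tau) ** 2
                 + model.z_delta * _wrist_rise(tau))

    # hand orientation: pronation released over the transport
    phi = _PRONATION_RAD * (1.0 - _minimum_jerk(tau))
    R = _rot_y(phi)

    ind1 = rad - np.einsum("nij,j->ni", R, _RAD_LOCAL)
    lit1 = ind1 + np.einsum("nij,j->ni", R, np.array([_LIT1_OFFSET, 0.0, 0.0]))

    # digit geometry in the hand frame
    gamma = 1.0 + _DIGIT_SEP_SLOPE * (tau - model.tau_bar)
    mid_off = 0.5 * (effects[3:6] + effects[6:9])  # common hand-posture offset
    m_loc = (model.m_mid[None, :]
             + gamma[:, None] * (model.m_class - model.m_mid)[None, :]
             + mid_off[None, :])

    delta = model.arc_rate * (tau - model.tau_bar)
    fp_off = effects[9:12]
    n_raw = (np.cos(delta)[:, None] * model.t0_hat[None, :]
             + np.sin(delta)[:, None] * model.arc_dir[None, :]
             + gamma[:, None] * model.fp_tilt[None, :]
             + fp_off[None, :])
    n_loc = _normalize(n_raw)
    u_dir = _normalize(model.d_hat[None, :]
                       - np.sum(model.d_hat * n_loc, axis=1, keepdims=True) * n_loc)

    aperture = _aperture_profile(tau, model.aperture_peak, model.aperture_end,
                                 model.aperture_peak_loc, model.aperture_start)
    aperture = np.maximum(aperture + model.aperture_delta * _aperture_rise(tau)
                          + _feature_vec(effects, "grip_aperture"),
                          _MIN_APERTURE)

    ind3_loc = m_loc + 0.5 * aperture[:, None] * u_dir
    thu4_loc = m_loc - 0.5 * aperture[:, None] * u_dir
    w_pl = np.cross(n_loc, u_dir)
    thu0_loc = m_loc + _THU0_ALONG * u_dir + _THU0_ACROSS * w_pl

    def to_global(loc: np.ndarray) -> np.ndarray:
        return ind1 + np.einsum("nij,nj->ni", R, loc)

    positions = {
        "rad": rad, "ind1": ind1, "lit1": lit1,
        "ind3": to_global(ind3_loc), "thu4": to_global(thu4_loc),
        "thu0": to_global(thu0_loc),
    }
    if rng is not None and config.marker_noise_sd > 0:
        for name in positions:
            positions[name] = positions[name] + rng.normal(
                0.0, config.marker_noise_sd, positions[name].shape)
    return time_ms, positions


_ZERO_EFFECTS = np.zeros(len(FEATURE_NAMES))


def _noiseless_extraction(config: SyntheticConfig, model: _ClassModel,
                          duration_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Epoch profiles (10, 12) and epoch positions tau_e of a noiseless trial."""
    time_ms, positions = _trial_positions(config, model, duration_ms,
                                          _ZERO_EFFECTS, None)
    trial = TrialRecording(trial_id="cal", participant_id="cal",
                           object_size=model.size, sampling_rate=config.sampling_rate,
                           time_ms=time_ms, positions=positions)
    t, series, seg = _features.trial_feature_series(trial, SegmentationParams())
    epochs = _preprocess.normalize_to_epochs(t, series, seg, EPOCH_PERCENTS)
    fp = epochs[:, 9:12]
    epochs[:, 9:12] = fp / np.linalg.norm(fp, axis=1, keepdims=True)
    t_epochs = seg.onset_time + EPOCH_PERCENTS / 100.0 * seg.movement_duration
    tau_e = (t_epochs - _PRE_MS) / duration_ms
    return epochs, tau_e


_CALIBRATION_CACHE: dict[tuple, _ClassModel] = {}


def calibrate_class_model(config: SyntheticConfig, size: str) -> _ClassModel:
    """Solve the class movement model so that noiseless extraction reproduces
    the configured grand means for wrist velocity (via the movement
    duration), wrist height (arch amplitude) and grip aperture (peak
    aperture).  Results are cached per configuration."""
    key = config._calibration_key(size)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]

    s = config.effect_scale
    targets = _class_targets(config, size)
    v_t = _feature_vec(targets, "wrist_velocity")
    wh_t = _feature_vec(targets, "wrist_height")
    ga_t = _feature_vec(targets, "grip_aperture")
    # size-neutral base targets (class midpoints of the configured means)
    wh_mid = 0.5 * sum(config.class_means["wrist_height"])
    ga_mid = 0.5 * sum(config.class_means["grip_aperture"])

    aperture_end = (0.5 * (_OBJECT_DIAMETER["small"] + _OBJECT_DIAMETER["large"])
                    + _CONTACT_MARGIN)
    kappa = s * _SPEED_ASYMMETRY[size]

    # finger-plane arc geometry from the configured class means
    fp_small = np.array([config.class_means[f][0] for f in
                         ("fingerplane_x", "fingerplane_y", "fingerplane_z")])
    fp_large = np.array([config.class_means[f][1] for f in
                         ("fingerplane_x", "fingerplane_y", "fingerplane_z")])
    t0 = 0.5 * (fp_small + fp_large)
    t_class = targets[9:12]
    t0_norm = float(np.linalg.norm(t0))
    t0_hat = t0 / t0_norm
    arc_dir = _normalize(np.array([t0_hat[1], -t0_hat[0], 0.0]))  # horizontal, _|_ t0

    idx = np.array([_feature_vec(targets, f) for f in ("index_x", "index_y", "index_z")])
    thb = np.array([_feature_vec(targets, f) for f in ("thumb_x", "thumb_y", "thumb_z")])
    d_hat = _normalize(idx - thb)
    m_class = 0.5 * (idx + thb)
    means_small = np.array([config.class_means[f][0] for f in FEATURE_NAMES])
    means_large = np.array([config.class_means[f][1] for f in FEATURE_NAMES])
    mid = 0.5 * (means_small + means_large)
    m_mid = 0.5 * (mid[3:6] + mid[6:9])

    model = _ClassModel(
        size=size, duration=config.mean_duration, kappa=kappa,
        aperture_peak=90.0, aperture_end=aperture_end, aperture_start=_APERTURE_START,
        aperture_peak_loc=_APERTURE_PEAK_LOC, aperture_delta=0.0,
        arch_height=max(wh_mid - _Z_START, 1.0) / 0.49, z_delta=0.0,
        targets=targets, t0_hat=t0_hat, t0_norm=t0_norm, arc_dir=arc_dir,
        fp_tilt=t_class - t0, arc_rate=0.8, d_hat=d_hat,
        m_class=m_class, m_mid=m_mid, tau_bar=0.55,
        tau_epochs=np.linspace(0.1, 1.0, 10), epoch_means=np.zeros((10, 12)),
    )

    def mean_speed_minus_target(T: float) -> float:
        epochs, _ = _noiseless_extraction(config, model, T)
        return float(epochs[:, 0].mean()) - v_t

    def solve_duration() -> None:
        model.duration = brentq(mean_speed_minus_target, 400.0, 3000.0, xtol=0.05)

    def _extracted_mean(feature_col: int) -> float:
        return float(_noiseless_extraction(config, model, model.duration)[0][:, feature_col].mean())

    def _solve_affine(attr: str, target: float, col: int, step: float) -> None:
        """One affine (secant) solve: extracted grand means are affine in the
        profile amplitudes to excellent approximation."""
        x0 = getattr(model, attr)
        y0 = _extracted_mean(col)
        setattr(model, attr, x0 + step)
        y1 = _extracted_mean(col)
        setattr(model, attr, x0 + (target - y0) * step / (y1 - y0))

    def solve_height() -> None:
        # size-neutral arch reproduces the class midpoint; the late-rise
        # term then carries the class difference
        model.z_delta = 0.0
        _solve_affine("arch_height", wh_mid, 1, 20.0)
        _solve_affine("z_delta", wh_t, 1, 10.0)

    def solve_aperture() -> None:
        _solve_affine("aperture_peak", ga_mid, 2, 30.0)
        _solve_affine("aperture_delta", ga_t, 2, 10.0)

    solve_duration()
    solve_height()
    solve_duration()
    solve_height()
    solve_duration()

    # epoch positions and finger-plane arc rate for the calibrated duration
    _, tau_e = _noiseless_extraction(config, model, model.duration)
    model.tau_epochs = tau_e
    model.tau_bar = float(tau_e.mean())

    def arc_residual(c1: float) -> float:
        return float(np.cos(c1 * (tau_e - model.tau_bar)).mean()) - t0_norm
    # widest admissible arc keeps cos well-defined and the mean above target
    model.arc_rate = brentq(arc_residual, 0.0, 2.5 / max(tau_e[-1] - model.tau_bar, 1e-6),
                            xtol=1e-6)

    solve_aperture()
    epochs, tau_e = _noiseless_extraction(config, model, model.duration)
    model.epoch_means = epochs
    model.tau_epochs = tau_e
    model.tau_bar = float(tau_e.mean())
    _CALIBRATION_CACHE[key] = model
    return model


def epoch_mean_profiles(config: SyntheticConfig, object_size: str) -> np.ndarray:
    """(10, 12) noiseless per-epoch feature means for one class — the
    calibration targets shared by marker mode and feature mode."""
    return calibrate_class_model(config, object_size).epoch_means.copy()


def _draw_trial_duration(config: SyntheticConfig, model: _ClassModel,
                         v_participant: float, v_trial_offset: float,
                         rng: np.random.Generator) -> tuple[float, float]:
    """Trial duration realizing the trial's wrist-velocity offset (speed
    scales inversely with duration), plus optional extra jitter.  Unrealizable
    (non-positive) draws are rejected and the trial-level offset redrawn a
    bounded number of times; the participant effect stays fixed."""
    v_class = _feature_vec(model.targets, "wrist_velocity")
    for _ in range(20):
        v_trial = v_class + v_participant + v_trial_offset
        if v_trial > 50.0:
            duration = model.duration * v_class / v_trial
            if config.duration_sd > 0:
                duration += rng.normal(0.0, config.duration_sd)
            if duration > 150.0:
                return duration, v_trial_offset
        v_trial_offset = rng.normal(
            0.0, config.trial_noise_sd.get("wrist_velocity", 0.0))
    raise ValueError("could not draw a positive trial duration after 20 attempts")


def simulate_trial_markers(config: SyntheticConfig, object_size: str,
                           participant_id: str = "p01",
                           rng: np.random.Generator | int | None = None,
                           participant_effects: np.ndarray | None = None,
                           trial_id: str = "t001") -> TrialRecording:
    """One synthetic trial's marker trajectories.

    ``participant_effects`` (a 12-vector of per-feature offsets) represents
    the participant's random effect; trial-level offsets and marker jitter
    are drawn from ``rng``.
    """
    if object_size not in OBJECT_SIZES:
        raise ValueError(f"object_size must be one of {OBJECT_SIZES}")
    rng = np.random.default_rng(rng)
    model = calibrate_class_model(config, object_size)
    eff_p = np.zeros(12) if participant_effects is None else np.asarray(participant_effects)
    eff_t = rng.normal(0.0, 1.0, 12) * config.sd_vector("trial")
    iv = FEATURE_NAMES.index("wrist_velocity")
    duration, eff_t[iv] = _draw_trial_duration(config, model, eff_p[iv], eff_t[iv], rng)
    effects = eff_p + eff_t
    time_ms, positions = _trial_positions(config, model, duration, effects, rng)
    return TrialRecording(
        trial_id=trial_id, participant_id=participant_id, object_size=object_size,
        sampling_rate=config.sampling_rate, time_ms=time_ms, positions=positions)


def simulate_dataset(config: SyntheticConfig) -> list[TrialRecording]:
    """Full marker-mode dataset: n_participants x 2 sizes x n_trials_per_size
    trials, with participant random effects shared across a participant's
    trials.  Deterministic under ``config.seed``."""
    for size in OBJECT_SIZES:   # calibrate up front (cached)
        calibrate_class_model(config, size)
    ss = np.random.SeedSequence(config.seed)
    part_seeds = ss.spawn(config.n_participants)
    psd = config.sd_vector("participant")
    trials: list[TrialRecording] = []
    k = 0
    for p in range(config.n_participants):
        prng = np.random.default_rng(part_seeds[p])
        pid = f"p{p + 1:02d}"
        eff_p = prng.normal(0.0, 1.0, 12) * psd
        for size in OBJECT_SIZES:
            for _ in range(config.n_trials_per_size):
                k += 1
                trials.append(simulate_trial_markers(
                    config, size, participant_id=pid, rng=prng,
                    participant_effects=eff_p, trial_id=f"t{k:04d}"))
    return trials


def simulate_feature_dataset(config: SyntheticConfig) -> EpochFeatureMatrix:
    """Epoch-level feature matrix drawn directly from the calibrated
    per-epoch mean profiles, with participant, trial and per-epoch noise.
    Finger-plane triplets are renormalized to unit length per epoch."""
    profiles = {size: epoch_mean_profiles(config, size) for size in OBJECT_SIZES}
    ss = np.random.SeedSequence(config.seed)
    part_seeds = ss.spawn(config.n_participants)
    psd = config.sd_vector("participant")
    tsd = config.sd_vector("trial")
    esd = tsd * config.epoch_noise_frac
    values, tids, pids, labels = [], [], [], []
    k = 0
    for p in range(config.n_participants):
        prng = np.random.default_rng(part_seeds[p])
        pid = f"p{p + 1:02d}"
        eff_p = prng.normal(0.0, 1.0, 12) * psd
        for size in OBJECT_SIZES:
            for _ in range(config.n_trials_per_size):
                k += 1
                eff_t = prng.normal(0.0, 1.0, 12) * tsd
                cell = prng.normal(0.0, 1.0, (10, 12)) * esd[None, :]
                v = profiles[size] + (eff_p + eff_t)[None, :] + cell
                fp = v[:, 9:12]
                v[:, 9:12] = fp / np.linalg.norm(fp, axis=1, keepdims=True)
                values.append(v)
                tids.append(f"t{k:04d}")
                pids.append(pid)
                labels.append(size)
    return EpochFeatureMatrix(
        values=np.stack(values), trial_ids=np.array(tids),
        participant_ids=np.array(pids), labels=np.array(labels),
        feature_names=FEATURE_NAMES)


def write_dataset(trials: list[TrialRecording], path: str | Path,
                  config: SyntheticConfig | None = None) -> None:
    """Write a marker-mode dataset as a trial-table TSV, plus a JSON sidecar
    recording the generator configuration and seed."""
    path = Path(path)
    _io.write_trials_tsv(trials, path)
    if config is not None:
        _io.write_config_sidecar(config.to_dict(), path.with_suffix(".config.json"))
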