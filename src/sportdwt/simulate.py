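"""Synthetic activity-log generator emulating the study's capture design.

No public accession exists for the original smartphone dataset, so this
module synthesises 9-second, activity-centred tri-axial logs for the seven
activities under the two phone profiles (16 Hz and 25 Hz, 8-bit), with
inter-subject variability, so the whole pipeline can be exercised and
tested end to end.

The signal model is deliberately simple and fully parameterised:

* locomotion (A1-A4) is a sum of sinusoids at the stride frequency and its
  first harmonics, with per-axis amplitudes growing from zero (stationary)
  to sprinting levels;
* game activities (A5-A7) superimpose damped-oscillation bursts centred at
  4.5 s on top of low-level shuffling motion, mimicking a player slowing
  down to play the ball; the outer seconds of a game log (more than 3 s
  from the centre) carry jog-like surrounding play, so analysis windows
  long enough to reach them mix two activities and become harder to
  classify — the reason long windows hurt in play that moves quickly from
  action to action;
* gravity contributes a constant 1 g offset on the vertical axis, rotated
  by a per-subject orientation perturbation (the phone sits on the upper
  back in a snug vest, so orientation is nearly fixed);
* each subject scales amplitudes and jitters stride frequency;
* Gaussian sensor noise is added and the result is quantized to the
  device's 8-bit grid over its +-range.

Two sport presets place the game-activity signatures on different axes
(soccer: lower-body impacts transmitted vertically; hockey: upper-arm
swings in the horizontal plane).  The ``separability`` knob controls how
distinct the three game activities are from each other: ``"high"`` gives
them well-separated burst frequencies and energies, ``"low"`` makes their
bursts similar in character so that A5-A7 confuse while A1-A4 stay
distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .signals import (ACTIVITY_LABELS, HTC_DESIRE, NEXUS_ONE,
                      AccelerometerRecording, ActivityLog, DeviceProfile,
                      LOG_DURATION_S)

__all__ = [
    "DeviceProfile", "NEXUS_ONE", "HTC_DESIRE", "BurstDescriptor",
    "ActivityModel", "SubjectProfile", "SportPreset", "simulate_log",
    "simulate_dataset",
]


@dataclass(frozen=True)
class BurstDescriptor:
    """Damped-oscillation burst(s) describing a game activity.

    ``count`` bursts of ``duration_s`` each, peak amplitude ``peak_g``,
    oscillating at ``carrier_hz`` (kept below the 8 Hz Nyquist limit of the
    slower device), distributed across the axes by ``axis_weights``.
    """

    count: int
    duration_s: float
    peak_g: float
    carrier_hz: float
    axis_weights: tuple[float, float, float] = (0.3, 0.3, 1.0)


@dataclass(frozen=True)
class ActivityModel:
    """Generative parameters for one activity label.

    ``speed_band`` is informational (m/s, matching the activity
    definitions: stationary 0, walking 1+-1, jogging 3.5+-1.5, sprinting
    5+); the kinematics that matter for the accelerometer are the stride
    frequency and per-axis amplitudes, plus an optional burst for game
    activities.
    """

    label: str
    speed_band: tuple[float, float]
    stride_hz: float
    amplitude_g: tuple[float, float, float]
    burst: Optional[BurstDescriptor] = None

    def __post_init__(self) -> None:
        if self.label not in ACTIVITY_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.speed_band[0] > self.speed_band[1]:
            raise ValueError("speed band must be (lo, hi)")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject variability: size/strength scaling, gait tempo jitter
    and a small orientation perturbation of the phone on the back."""

    amplitude_scale: float = 1.0
    frequency_jitter: float = 1.0
    tilt_pitch_rad: float = 0.0
    tilt_roll_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")

    @classmethod
    def sample(cls, rng: np.random.Generator) -> "SubjectProfile":
        return cls(
            amplitude_scale=float(np.exp(rng.normal(0.0, 0.15))),
            frequency_jitter=float(np.clip(rng.normal(1.0, 0.06), 0.8, 1.2)),
            tilt_pitch_rad=float(rng.normal(0.0, np.deg2rad(4.0))),
            tilt_roll_rad=float(rng.normal(0.0, np.deg2rad(4.0))),
        )


# baseline inertial models shared by both sports
_INERTIAL = {
    "A1": ActivityModel("A1", (0.0, 0.0), 0.0, (0.0, 0.0, 0.0)),
    "A2": ActivityModel("A2", (0.0, 2.0), 1.0, (0.12, 0.08, 0.30)),
    "A3": ActivityModel("A3", (2.0, 5.0), 2.5, (0.30, 0.20, 0.80)),
    "A4": ActivityModel("A4", (5.0, 9.0), 3.5, (0.55, 0.40, 1.60)),
}

# light shuffling under game activities: the player slows to play the ball,
# so the background movement sits well below walking level and tempo
_GAME_BASE = {"stride_hz": 0.8, "amplitude_g": (0.05, 0.035, 0.10)}

# axis emphasis of the game-activity signatures.  With high separability
# each activity loads a different axis (kick vertical, tackle
# anterior-posterior, dribble medio-lateral for soccer; the hockey mapping
# shifts the emphasis to arm-driven horizontal axes).  With low
# separability all three share the sport's generic placement, so they can
# only be told apart by their (then similar) burst spectra.
_HIGH_AXES: dict[str, dict[str, tuple[float, float, float]]] = {
    "soccer": {"A5": (0.40, 0.15, 1.00),
               "A6": (1.00, 0.60, 0.25),
               "A7": (0.25, 1.00, 0.40)},
    "hockey": {"A5": (1.00, 0.50, 0.25),
               "A6": (0.30, 1.00, 0.50),
               "A7": (0.55, 0.30, 1.00)},
}
_LOW_AXES: dict[str, tuple[float, float, float]] = {
    "soccer": (0.50, 0.20, 1.00),
    "hockey": (1.00, 0.80, 0.35),
}

# jog-like motion in the outer seconds of game logs (surrounding play);
# windows wider than 2 * _CLEAN_HALFSPAN_S mix it into the activity
_CLEAN_HALFSPAN_S = 3.0
_SURROUNDING_PLAY = ActivityModel("A3", (2.0, 5.0), 2.5, (0.24, 0.16, 0.64))


@dataclass(frozen=True)
class SportPreset:
    """Named, versioned generator preset for one sport.

    ``separability`` in {"high", "low"} controls how distinguishable the
    game activities A5-A7 are from one another.
    """

    sport: str
    separability: str = "high"
    version: str = "1"

    def __post_init__(self) -> None:
        if self.sport not in ("soccer", "hockey"):
            raise ValueError("sport must be 'soccer' or 'hockey'")
        if self.separability not in ("high", "low"):
            raise ValueError("separability must be 'high' or 'low'")

    def activity_models(self) -> dict[str, ActivityModel]:
        if self.separability == "high":
            # ball hit: one sharp high-frequency impact; tackle: a single
            # slow heavy lunge; dribble: a train of light taps.  Carriers
            # are chosen to fall in the same dyadic band at both device
            # rates (7 Hz -> D1, 3.5 Hz -> D2 at level 2 for 16 and 25 Hz)
            axes = _HIGH_AXES[self.sport]
            bursts = {
                "A5": BurstDescriptor(1, 0.6, 3.0, 7.0, axes["A5"]),
                "A6": BurstDescriptor(1, 1.5, 1.8, 3.5, axes["A6"]),
                "A7": BurstDescriptor(6, 0.3, 0.9, 7.0, axes["A7"]),
            }
        else:
            # bursts of similar energy, band and axis placement: the three
            # game activities remain distinct from locomotion but blur
            # into one another
            axes = _LOW_AXES[self.sport]
            bursts = {
                "A5": BurstDescriptor(1, 1.0, 1.70, 5.2, axes),
                "A6": BurstDescriptor(1, 1.2, 1.55, 4.6, axes),
                "A7": BurstDescriptor(2, 1.0, 1.60, 4.9, axes),
            }
        models = dict(_INERTIAL)
        for label, burst in bursts.items():
            models[label] = ActivityModel(
                label=label,
                speed_band=(0.0, 3.0),
                stride_hz=_GAME_BASE["stride_hz"],
                amplitude_g=_GAME_BASE["amplitude_g"],
                burst=burst,
            )
        return models


def _rotation(pitch: float, roll: float) -> np.ndarray:
    cp, sp = np.cos(pitch), np.sin(pitch)
    cr, sr = np.cos(roll), np.sin(roll)
    rx = np.array([[1, 0, 0], [0, cp, -sp], [0, sp, cp]])
    ry = np.array([[cr, 0, sr], [0, 1, 0], [-sr, 0, cr]])
    return rx @ ry


def _gait(t: np.ndarray, model: ActivityModel, subject: SubjectProfile,
          rng: np.random.Generator) -> np.ndarray:
    """Sum-of-sinusoids locomotion signal, shape (n, 3)."""
    out = np.zeros((len(t), 3))
    if model.stride_hz <= 0:
        return out
    f = model.stride_hz * subject.frequency_jitter
    for a in range(3):
        amp = model.amplitude_g[a] * subject.amplitude_scale
        if amp == 0:
            continue
        for h in (1, 2, 3):
            phase = rng.uniform(0, 2 * np.pi)
            out[:, a] += amp * 0.6 ** (h - 1) * np.sin(
                2 * np.pi * f * h * t + phase
            )
    return out


def _bursts(t: np.ndarray, burst: BurstDescriptor, subject: SubjectProfile,
            rng: np.random.Generator) -> np.ndarray:
    """Damped oscillations centred on the middle of the log, shape (n, 3)."""
    center = LOG_DURATION_S / 2.0
    span = burst.count * burst.duration_s * 1.3
    starts = center - span / 2.0 + np.arange(burst.count) * span / burst.count
    tau = burst.duration_s / 3.0
    env = np.zeros(len(t))
    for s in starts:
        s = s + rng.normal(0.0, 0.05)
        dt = t - s
        active = dt >= 0
        env_i = np.zeros(len(t))
        env_i[active] = np.exp(-dt[active] / tau) * np.sin(
            2 * np.pi * burst.carrier_hz * dt[active]
        )
        env += env_i
    peak = burst.peak_g * subject.amplitude_scale
    return peak * env[:, None] * np.asarray(burst.axis_weights)[None, :]


def _quantize(values: np.ndarray, device: DeviceProfile) -> np.ndarray:
    step = 2.0 * device.range_g / (2 ** device.resolution_bits)
    clipped = np.clip(values, -device.range_g, device.range_g - step)
    return np.round(clipped / step) * step


def simulate_log(activity: ActivityModel, subject: SubjectProfile,
                 device: DeviceProfile, seed: int) -> ActivityLog:
    """Generate one 9-second activity-centred log; deterministic per seed."""
    rng = np.random.default_rng(seed)
    n = int(round(LOG_DURATION_S * device.sampling_rate))
    t = np.arange(n) / device.sampling_rate
    sig = _gait(t, activity, subject, rng)
    if activity.burst is not None:
        sig += _bursts(t, activity.burst, subject, rng)
        # surrounding play: the player jogs into and out of the ball
        # contact, so the log's outer seconds look like locomotion
        jog = _gait(t, _SURROUNDING_PLAY, subject, rng)
        mask = np.abs(t - LOG_DURATION_S / 2.0) > _CLEAN_HALFSPAN_S
        sig += jog * mask[:, None]
    gravity = _rotation(subject.tilt_pitch_rad, subject.tilt_roll_rad) @ \
        np.array([0.0, 0.0, 1.0])
    sig += gravity[None, :]
    if device.noise_sd > 0:
        sig = sig + rng.normal(0.0, device.noise_sd, size=sig.shape)
    sig = _quantize(sig, device)
    rec = AccelerometerRecording(
        device_id=device.name, sampling_rate=device.sampling_rate,
        t=t, ax=sig[:, 0], ay=sig[:, 1], az=sig[:, 2],
    )
    return ActivityLog(recording=rec, label=activity.label,
                       activity_center=float(t[n // 2]))


def simulate_dataset(preset: SportPreset, n_per_activity: int = 30,
                     n_subjects: int = 15,
                     devices: Sequence[DeviceProfile] = (NEXUS_ONE, HTC_DESIRE),
                     seed: int = 0) -> list[ActivityLog]:
    """Generate a balanced labelled dataset (7 x n_per_activity logs).

    Subjects are drawn once from a seeded profile distribution and assigned
    to logs at random, mimicking the multi-player capture; devices
    alternate through ``devices``.  The default size matches the study
    design of 30 examples per activity, i.e. 210 logs per sport.
    """
    if n_per_activity < 2:
        raise ValueError("n_per_activity must be >= 2")
    rng = np.random.default_rng(seed)
    subjects = [SubjectProfile.sample(rng) for _ in range(n_subjects)]
    models = preset.activity_models()
    logs: list[ActivityLog] = []
    for label in ACTIVITY_LABELS:
        for j in range(n_per_activity):
            subject = subjects[int(rng.integers(n_subjects))]
            device = devices[int(rng.integers(len(devices)))]
            log_seed = int(rng.integers(2 ** 31))
            log = simulate_log(models[label], subject, device, log_seed)
            logs.append(replace(log, log_id=f"{preset.sport}_{label}_{j:03d}"))
    return logs
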