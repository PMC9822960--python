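"""Acquisition protocols and per-subject signal parameters.

A :class:`Protocol` is the timed phase schedule a recording session follows:
alternating rest and active phases, each with a label and a duration.  The
default gesture protocol mirrors a common armband study design — 15 s of rest
followed by 15 s of gesture execution, repeated 6 times for each of four
active gestures (pinch, tripod, power, finger extension), with rest as the
fifth class.  The default force protocol alternates 15 s of rest with a 15 s
clench-force ramp, repeated 10 times.

:class:`SubjectParams` collects the phenomenological constants that map a
subject's muscle activation onto sensor readings: per-channel per-gesture
luminosity deflection gains for the green and infrared LEDs of a five-module
LMG armband, per-channel baselines, a first-order tissue time constant,
optional slow drift, sensor noise levels, and EMG modulation gains for five
bipolar surface-EMG channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError

REST = "rest"
DEFAULT_GESTURES = ("pinch", "tripod", "power", "extension")

#: LED multiplexing interval of the armband firmware (green/IR alternation).
DEFAULT_LED_TOGGLE_MS = 125.0
#: Photodiode ADC rate (gives 50 fresh samples per LED state at 125 ms).
DEFAULT_LMG_RATE = 400.0
#: Bipolar sEMG amplifier rate.
DEFAULT_EMG_RATE = 1200.0


@dataclass(frozen=True)
class Protocol:
    """Timed phase schedule of one recording session.

    Parameters
    ----------
    phase_schedule
        Ordered ``(label, duration_s)`` pairs, alternating rest and active
        phases.
    n_repetitions
        Number of repetitions of each active phase.
    gestures
        Ordered set of active labels (rest excluded).
    """

    phase_schedule: tuple[tuple[str, float], ...]
    n_repetitions: int
    gestures: tuple[str, ...]
    sample_rate_lmg: float = DEFAULT_LMG_RATE
    sample_rate_emg: float = DEFAULT_EMG_RATE
    led_toggle_ms: float = DEFAULT_LED_TOGGLE_MS

    def __post_init__(self) -> None:
        if not self.gestures:
            raise ConfigError("protocol needs at least one active gesture")
        if self.n_repetitions < 1:
            raise ConfigError("n_repetitions must be >= 1")
        if self.led_toggle_ms <= 0:
            raise ConfigError("led_toggle_ms must be positive")
        if any(d <= 0 for _, d in self.phase_schedule):
            raise ConfigError("all phase durations must be positive")
        for i, (label, _) in enumerate(self.phase_schedule):
            expect_rest = i % 2 == 0
            if expect_rest != (label == REST):
                raise ConfigError(
                    "phase schedule must alternate rest and active phases; "
                    f"phase {i} is {label!r}"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        """Full label set: rest followed by the active gestures."""
        return (REST,) + tuple(self.gestures)

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.phase_schedule))


def make_gesture_protocol(
    rest_s: float = 15.0,
    gesture_s: float = 15.0,
    n_reps: int = 6,
    gestures: tuple[str, ...] = DEFAULT_GESTURES,
    **kwargs,
) -> Protocol:
    """Build the gesture-classification protocol.

    Each active gesture is preceded by a rest phase and the (rest, gesture)
    pair is repeated ``n_reps`` times before moving to the next gesture, so
    the schedule has ``2 * n_reps * len(gestures)`` phases.
    """
    if not gestures:
        raise ConfigError("gesture list must be non-empty")
    schedule: list[tuple[str, float]] = []
    for g in gestures:
        for _ in range(n_reps):
            schedule.append((REST, float(rest_s)))
            schedule.append((g, float(gesture_s)))
    return Protocol(tuple(schedule), n_reps, tuple(gestures), **kwargs)


def make_force_protocol(
    rest_s: float = 15.0,
    ramp_s: float = 15.0,
    n_reps: int = 10,
    **kwargs,
) -> Protocol:
    """Build the clench-force ramp protocol: rest / ramp-to-half-max, x n_reps."""
    schedule: list[tuple[str, float]] = []
    for _ in range(n_reps):
        schedule.append((REST, float(rest_s)))
        schedule.append(("clench", float(ramp_s)))
    return Protocol(tuple(schedule), n_reps, ("clench",), **kwargs)


@dataclass(frozen=True)
class SubjectParams:
    """Phenomenological subject constants for the signal simulator.

    Gain matrices are ``[5 channels x K labels]`` with column order matching
    ``labels`` (rest first); the rest column must be zero.  ``tau_deform_ms``
    is the first-order tissue-deformation time constant.
    """

    labels: tuple[str, ...]
    gain_green: np.ndarray  # [5, K] luminosity deflection, a.u.
    gain_ir: np.ndarray  # [5, K] a.u.
    baseline: np.ndarray  # [5] a.u.
    emg_gain: np.ndarray  # [5, K] mV
    tau_deform_ms: float = 150.0
    drift_amp: float = 0.0  # a.u.; 0 disables drift
    drift_period_s: float = 60.0
    noise_sd_lmg: float = 0.0  # a.u.
    noise_sd_emg: float = 0.0  # mV
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gain_green", "gain_ir", "emg_gain", "baseline"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        k = len(self.labels)
        if self.labels[0] != REST:
            raise ConfigError("labels must start with 'rest'")
        for name in ("gain_green", "gain_ir", "emg_gain"):
            m = getattr(self, name)
            if m.shape != (self.n_channels, k):
                raise ConfigError(f"{name} must have shape ({self.n_channels}, {k})")
            if np.any(m[:, 0] != 0.0):
                raise ConfigError(f"{name} rest column must be all zero")
            # distinct gestures must produce distinct deflection patterns
            for a in range(1, k):
                for b in range(a + 1, k):
                    if np.array_equal(m[:, a], m[:, b]):
                        raise ConfigError(
                            f"{name} columns for {self.labels[a]!r} and "
                            f"{self.labels[b]!r} are identical"
                        )
        if self.tau_deform_ms <= 0:
            raise ConfigError("tau_deform_ms must be positive")
        if self.noise_sd_lmg < 0 or self.noise_sd_emg < 0:
            raise ConfigError("noise SDs must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.baseline.shape[0]

    def column(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ConfigError(f"unknown gesture label {label!r}") from None

    def with_(self, **kwargs) -> "SubjectParams":
        return replace(self, **kwargs)


def default_subject_params(
    gestures: tuple[str, ...] = DEFAULT_GESTURES,
    seed: int = 42,
    noise_level: float = 0.05,
    drift: bool = False,
    n_channels: int = 5,
    min_column_distance: float = 0.4,
) -> SubjectParams:
    """Draw a synthetic subject with well-separated per-gesture gain columns.

    Gains are sampled uniformly on [0.3, 1.0] a.u. (LMG) and [0.3, 1.5] mV
    (EMG) per channel; any active column closer than ``min_column_distance``
    (Euclidean) to an earlier column is redrawn, so distinct gestures deform
    the five sensing sites in distinct patterns.  Noise standard deviations
    are ``noise_level`` times the mean active gain.
    """
    rng = np.random.default_rng(seed)
    labels = (REST,) + tuple(gestures)
    k = len(labels)

    def draw(lo: float, hi: float) -> np.ndarray:
        m = np.zeros((n_channels, k))
        for j in range(1, k):
            for _ in range(1000):
                col = rng.uniform(lo, hi, size=n_channels)
                d = [np.linalg.norm(col - m[:, i]) for i in range(1, j)]
                if not d or min(d) >= min_column_distance:
                    m[:, j] = col
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise ConfigError("could not draw separated gain columns")
        return m

    gain_green = draw(0.3, 1.0)
    gain_ir = draw(0.3, 1.0)
    emg_gain = draw(0.3, 1.5)
    baseline = 2.0 + rng.uniform(0.0, 0.4, size=n_channels)
    scale = float(gain_green[:, 1:].mean())
    return SubjectParams(
        labels=labels,
        gain_green=gain_green,
        gain_ir=gain_ir,
        baseline=baseline,
        emg_gain=emg_gain,
        drift_amp=0.02 * scale if drift else 0.0,
        noise_sd_lmg=noise_level * scale,
        noise_sd_emg=noise_level * float(emg_gain[:, 1:].mean()),
        seed=seed,
    )
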