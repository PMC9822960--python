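"""Seeded simulation of LMG armband, surface-EMG, and grip-force sessions.

The optical model is phenomenological: muscle activation during a gesture is
a 0/1 indicator smoothed by a first-order tissue lag (time constant
``tau_deform_ms``), and each photodiode channel deflects from its baseline by
a gesture- and LED-colour-specific gain times that envelope.  The armband
time-multiplexes one green and one infrared LED per module, toggling every
``led_toggle_ms`` while the photodiode is read continuously, so the raw
record is a single 5-channel track plus an LED-state track.  EMG channels
are band-limited carrier noise (20-450 Hz) amplitude-modulated by the same
activation envelope, plus white measurement noise.  Grip-force sessions
replace the binary indicator with a triangular ramp from rest to half of
maximum clench and back.

All randomness flows from one integer seed through `numpy.random.SeedSequence`,
so identical inputs give bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, ContractError
from .protocols import REST, Protocol, SubjectParams

GREEN = "green"
IR = "ir"

#: Synthesis band of the EMG carrier noise (Hz). Deliberately narrower than
#: the 5-500 Hz analysis filter so the filtering stage is exercised.
EMG_CARRIER_BAND = (20.0, 450.0)


@dataclass
class MultiplexedLMG:
    """Raw photodiode samples before green/IR separation.

    ``samples[t, c]`` is the reading of module ``c`` while the LED named in
    ``led_state[t]`` is lit.  ``trigger`` and ``repetition_id`` share the
    sample grid.
    """

    samples: np.ndarray  # [T, 5] a.u.
    led_state: np.ndarray  # [T] str in {green, ir}
    sample_rate: float
    toggle_ms: float
    trigger: np.ndarray  # [T] str labels
    repetition_id: np.ndarray  # [T] int
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        t = self.samples.shape[0]
        if t < 1:
            raise ContractError("MultiplexedLMG needs at least one sample")
        for name in ("led_state", "trigger", "repetition_id"):
            if getattr(self, name).shape[0] != t:
                raise ContractError(f"{name} length must match samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass
class SessionRecording:
    """Uniformly sampled multichannel recording with a per-sample label track."""

    signal: np.ndarray  # [T, C]
    trigger: np.ndarray  # [T] str labels
    repetition_id: np.ndarray  # [T] int
    sample_rate: float
    modality: str  # "lmg" | "emg"
    subject_id: str = "synthetic"
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        t = self.signal.shape[0]
        if self.trigger.shape[0] != t or self.repetition_id.shape[0] != t:
            raise ContractError("trigger/repetition_id length must match signal")
        if not self.channel_names:
            self.channel_names = tuple(
                f"ch{i + 1:02d}" for i in range(self.signal.shape[1])
            )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]


@dataclass
class ForceTrace:
    """Grip force normalized to maximum voluntary clench (0-1)."""

    force: np.ndarray  # [T]
    sample_rate: float

    def __post_init__(self) -> None:
        if np.any(self.force < 0) or np.any(self.force > 1):
            raise ContractError("force must lie in [0, 1]")


@dataclass
class GestureSession:
    lmg: MultiplexedLMG
    emg: SessionRecording


@dataclass
class ForceSession:
    lmg: MultiplexedLMG
    force: ForceTrace


def first_order_lag(target: np.ndarray, tau_ms: float, sample_rate: float) -> np.ndarray:
    """First-order response toward ``target``: e += (target - e)(1 - exp(-dt/tau)).

    The target is held over each sample interval, so a unit step reaches
    ``1 - exp(-t/tau)`` exactly ``t`` after the first active sample.
    """
    if tau_ms <= 0:
        raise ConfigError("tau must be positive")
    target = np.asarray(target, dtype=float)
    a = 1.0 - np.exp(-1000.0 / (tau_ms * sample_rate))
    held = np.concatenate(([target[0]], target[:-1]))
    zi = np.array([(1.0 - a) * target[0]])
    env, _ = sps.lfilter([a], [1.0, -(1.0 - a)], held, zi=zi)
    return np.clip(env, 0.0, 1.0)


def activation_envelope(
    trigger: np.ndarray, tau_ms: float, sample_rate: float, labels=None
) -> dict[str, np.ndarray]:
    """Per-gesture first-order activation envelopes from the label track.

    Each active label's 0/1 indicator is low-pass smoothed with the tissue
    time constant, so activation rises during its phases and relaxes during
    the following rest instead of switching instantaneously.
    """
    trigger = np.asarray(trigger)
    if labels is None:
        labels = [l for l in np.unique(trigger) if l != REST]
    return {
        g: first_order_lag((trigger == g).astype(float), tau_ms, sample_rate)
        for g in labels
    }


def build_trigger(protocol: Protocol, sample_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample-grid label and repetition tracks for a protocol.

    Each (rest, active) phase pair shares the repetition index of its active
    phase, counted per active label from 1.
    """
    labels: list[np.ndarray] = []
    reps: list[np.ndarray] = []
    counters: dict[str, int] = {}
    sched = protocol.phase_schedule
    for i in range(0, len(sched), 2):
        active_label = sched[i + 1][0]
        counters[active_label] = counters.get(active_label, 0) + 1
        rep = counters[active_label]
        for label, dur in (sched[i], sched[i + 1]):
            n = int(round(dur * sample_rate))
            labels.append(np.full(n, label, dtype="U16"))
            reps.append(np.full(n, rep, dtype=np.int64))
    return np.concatenate(labels), np.concatenate(reps)


def build_led_state(n_samples: int, toggle_ms: float, sample_rate: float) -> np.ndarray:
    run = int(round(toggle_ms * sample_rate / 1000.0))
    if run < 1:
        raise ConfigError("led toggle interval shorter than one sample")
    n_runs = -(-n_samples // run)
    states = np.tile(np.repeat([GREEN, IR], run), -(-n_runs // 2) + 1)
    return states[:n_samples].astype("U5")


def _envelope_matrix(
    trigger: np.ndarray, params: SubjectParams, sample_rate: float
) -> np.ndarray:
    """[T, K] envelope per label column (rest column stays zero)."""
    env = np.zeros((trigger.shape[0], len(params.labels)))
    for g, e in activation_envelope(
        trigger, params.tau_deform_ms, sample_rate, labels=params.labels[1:]
    ).items():
        env[:, params.column(g)] = e
    return env


def _drift(params: SubjectParams, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # phases drawn even when drift is off, keeping downstream streams stable
    phases = rng.uniform(0.0, 2 * np.pi, size=params.n_channels)
    if params.drift_amp == 0.0:
        return np.zeros((t.shape[0], params.n_channels))
    return params.drift_amp * np.sin(
        2 * np.pi * t[:, None] / params.drift_period_s + phases[None, :]
    )


def _lmg_from_envelope(
    env: np.ndarray,
    params: SubjectParams,
    sample_rate: float,
    toggle_ms: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    t_n = env.shape[0]
    led = build_led_state(t_n, toggle_ms, sample_rate)
    defl_green = env @ params.gain_green.T  # [T, 5]
    defl_ir = env @ params.gain_ir.T
    green_mask = (led == GREEN)[:, None]
    t_s = np.arange(t_n) / sample_rate
    samples = (
        params.baseline[None, :]
        + np.where(green_mask, defl_green, defl_ir)
        + _drift(params, t_s, rng)
    )
    if params.noise_sd_lmg > 0:
        samples = samples + rng.normal(0.0, params.noise_sd_lmg, samples.shape)
    return samples, led


def simulate_gesture_session(
    protocol: Protocol,
    params: SubjectParams,
    seed: int | None = None,
    subject_id: str = "synthetic",
) -> GestureSession:
    """Simulate one multiplexed-LMG + 5-channel-EMG gesture session.

    Both modalities follow the same protocol on their own sample grids and
    share the subject's activation dynamics; identical ``(protocol, params,
    seed)`` give bit-identical output.
    """
    for g in protocol.gestures:
        params.column(g)  # validates label coverage
    ss = np.random.SeedSequence(params.seed if seed is None else seed)
    rng_lmg, rng_emg = (np.random.default_rng(c) for c in ss.spawn(2))

    trig_l, rep_l = build_trigger(protocol, protocol.sample_rate_lmg)
    env_l = _envelope_matrix(trig_l, params, protocol.sample_rate_lmg)
    samples, led = _lmg_from_envelope(
        env_l, params, protocol.sample_rate_lmg, protocol.led_toggle_ms, rng_lmg
    )
    lmg = MultiplexedLMG(
        samples, led, protocol.sample_rate_lmg, protocol.led_toggle_ms,
        trig_l, rep_l, subject_id,
    )

    fs_e = protocol.sample_rate_emg
    trig_e, rep_e = build_trigger(protocol, fs_e)
    env_e = _envelope_matrix(trig_e, params, fs_e)
    amplitude = env_e @ params.emg_gain.T  # [T, 5]
    carrier = rng_emg.standard_normal(amplitude.shape)
    sos = sps.butter(4, EMG_CARRIER_BAND, btype="bandpass", fs=fs_e, output="sos")
    carrier = sps.sosfilt(sos, carrier, axis=0)
    std = carrier.std(axis=0)
    carrier = carrier / np.where(std > 0, std, 1.0)
    emg_sig = amplitude * carrier
    if params.noise_sd_emg > 0:
        emg_sig = emg_sig + rng_emg.normal(0.0, params.noise_sd_emg, emg_sig.shape)
    emg = SessionRecording(emg_sig, trig_e, rep_e, fs_e, "emg", subject_id)
    return GestureSession(lmg=lmg, emg=emg)


def triangular_force(protocol: Protocol, sample_rate: float, peak: float = 0.5) -> np.ndarray:
    """Per-phase force track: zero at rest, symmetric ramp 0 -> peak -> 0 when active."""
    parts: list[np.ndarray] = []
    for label, dur in protocol.phase_schedule:
        n = int(round(dur * sample_rate))
        if label == REST:
            parts.append(np.zeros(n))
        else:
            k = np.arange(n)
            parts.append(peak * (1.0 - np.abs(2.0 * k / n - 1.0)))
    return np.concatenate(parts)


def simulate_force_session(
    protocol: Protocol,
    params: SubjectParams,
    seed: int | None = None,
    subject_id: str = "synthetic",
    peak: float = 0.5,
) -> ForceSession:
    """Simulate a clench-force ramp session with time-aligned LMG readings.

    The normalized force (fraction of maximum clench) drives the tissue
    envelope directly — deflection is ``gain * lag(force / peak)`` — so the
    LMG deflection tracks the ramp up to the first-order lag.
    """
    if len(protocol.gestures) != 1:
        raise ConfigError("force protocol must have exactly one active label")
    grasp = protocol.gestures[0]
    col = params.column(grasp)
    ss = np.random.SeedSequence(params.seed if seed is None else seed)
    rng_lmg = np.random.default_rng(ss.spawn(1)[0])

    fs = protocol.sample_rate_lmg
    trig, rep = build_trigger(protocol, fs)
    force = triangular_force(protocol, fs, peak)
    env_col = first_order_lag(force / peak, params.tau_deform_ms, fs)
    env = np.zeros((force.shape[0], len(params.labels)))
    env[:, col] = env_col
    samples, led = _lmg_from_envelope(env, params, fs, protocol.led_toggle_ms, rng_lmg)
    lmg = MultiplexedLMG(
        samples, led, fs, protocol.led_toggle_ms, trig, rep, subject_id
    )
    return ForceSession(lmg=lmg, force=ForceTrace(force, fs))
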