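"""End-to-end synthetic benchmarks chaining every pipeline stage.

`run_gesture_benchmark` simulates one synthetic subject performing the
default protocol (15 s rest / 15 s gesture, 6 repetitions of each of four
active gestures, 5 % sensor noise), demultiplexes the LMG track, extracts
strictly-labelled 200 ms / 20 ms windows, balances the five classes, and
runs repetition-blocked 5-fold CV for the requested decoder families — raw
windows for LMG, the 8-feature table for EMG.  `run_force_benchmark` does
the force counterpart: ten clench ramps, active-phase windows only, and
leave-one-repetition-out 10-fold CV reporting NMSE and Pearson r.

Both default to the reduced (CPU-sized) model preset and a seeded training
subsample; pass ``reduced=False`` for the full-size architectures.
"""

from __future__ import annotations

import logging

import numpy as np

from .decoders import ModelSpec, TrainConfig
from .errors import ConfigError
from .evaluation import CVReport, crossval_classification, crossval_regression
from .features import feature_table
from .preprocessing import balance_classes, butterworth_bandpass, demultiplex, slide_windows
from .protocols import (
    DEFAULT_GESTURES,
    default_subject_params,
    make_force_protocol,
    make_gesture_protocol,
)
from .simulate import simulate_force_session, simulate_gesture_session

log = logging.getLogger(__name__)


def _spec(family: str, task: str, seed: int, reduced: bool) -> ModelSpec:
    maker = ModelSpec.reduced if reduced else ModelSpec
    return maker(family=family, task=task, seed=seed)


def _cfg(seed: int, reduced: bool) -> TrainConfig:
    return TrainConfig.reduced(seed=seed) if reduced else TrainConfig(seed=seed)


def gesture_windows(seed: int = 42, noise_level: float = 0.05,
                    label_policy: str = "strict", n_reps: int = 6):
    """Simulate, demultiplex, window, and balance one gesture session.

    Returns ``(lmg_windows, emg_features)`` ready for the decoders.
    """
    protocol = make_gesture_protocol(n_reps=n_reps)
    params = default_subject_params(DEFAULT_GESTURES, seed=seed,
                                    noise_level=noise_level)
    session = simulate_gesture_session(protocol, params, seed=seed)

    lmg = demultiplex(session.lmg)
    ws_lmg = balance_classes(
        slide_windows(lmg, label_policy=label_policy),
        seed=seed, expected_labels=protocol.labels,
    )

    emg = session.emg
    emg.signal = butterworth_bandpass(
        emg.signal, 5.0, 500.0, order=4, sample_rate=emg.sample_rate
    )
    ws_emg = balance_classes(
        slide_windows(emg, label_policy=label_policy),
        seed=seed, expected_labels=protocol.labels,
    )
    return ws_lmg, feature_table(ws_emg)


def run_gesture_benchmark(
    seed: int = 42,
    families: tuple[str, ...] = ("rf", "cnn", "tmcvit"),
    modality: str = "lmg",
    reduced: bool = True,
    k: int = 5,
    noise_level: float = 0.05,
    n_reps: int = 6,
) -> dict[str, CVReport]:
    """Repetition-blocked k-fold classification CV per decoder family."""
    ws_lmg, ft_emg = gesture_windows(seed=seed, noise_level=noise_level,
                                     n_reps=n_reps)
    if modality == "lmg":
        x, labels, reps = ws_lmg, ws_lmg.labels, ws_lmg.repetition_ids
    elif modality == "emg":
        x, labels, reps = ft_emg, ft_emg.labels, ft_emg.repetition_ids
    else:
        raise ConfigError(f"unknown modality {modality!r}")
    out: dict[str, CVReport] = {}
    for fam in families:
        spec = _spec(fam, "classification", seed, reduced)
        log.info("gesture CV: %s on %s", fam, modality)
        out[fam] = crossval_classification(
            x, labels, reps, spec, k=k, seed=seed, cfg=_cfg(seed, reduced)
        )
    return out


def force_windows(seed: int = 42, noise_level: float = 0.05, n_reps: int = 10):
    """Simulate and window one force session; active-phase windows only."""
    protocol = make_force_protocol(n_reps=n_reps)
    params = default_subject_params(("clench",), seed=seed,
                                    noise_level=noise_level)
    session = simulate_force_session(protocol, params, seed=seed)
    lmg = demultiplex(session.lmg)
    ws = slide_windows(lmg, label_policy="strict", targets=session.force.force)
    active = np.flatnonzero(ws.labels != "rest")
    return ws.select(active)


def run_force_benchmark(
    seed: int = 42,
    family: str = "tmcvit",
    reduced: bool = True,
    folds: int = 10,
    noise_level: float = 0.05,
) -> CVReport:
    """Leave-one-repetition-out force regression CV (NMSE % and Pearson r)."""
    ws = force_windows(seed=seed, noise_level=noise_level, n_reps=folds)
    spec = _spec(family, "regression", seed, reduced)
    log.info("force CV: %s over %d folds", family, folds)
    return crossval_regression(
        ws, ws.targets, ws.repetition_ids, spec,
        folds=folds, seed=seed, cfg=_cfg(seed, reduced),
    )
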