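"""Session CSV format with a JSON metadata sidecar.

A session is stored as ``<name>.csv`` (columns ``time_s``, the channel
columns, ``led_state`` for multiplexed LMG, ``trigger``, ``repetition``,
and optionally ``force``) plus ``<name>.json`` describing modality, sample
rate, subject, channel names, and a provenance hash.  Numeric columns are
written at full double precision so write/read round-trips are lossless.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .simulate import ForceSession, ForceTrace, MultiplexedLMG, SessionRecording

_FLOAT_FMT = "%.17g"


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def _provenance(meta: dict) -> str:
    return hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_session(obj, path, force: np.ndarray | None = None,
                  extra_meta: dict | None = None) -> Path:
    """Write a session (and optional aligned force track) as CSV + sidecar."""
    path = Path(path)
    if isinstance(obj, ForceSession):
        return write_session(obj.lmg, path, force=obj.force.force,
                             extra_meta=extra_meta)
    if isinstance(obj, MultiplexedLMG):
        modality = "lmg-mux"
        signal = obj.samples
        names = [f"ch{i + 1:02d}" for i in range(signal.shape[1])]
        toggle_ms = obj.toggle_ms
    elif isinstance(obj, SessionRecording):
        modality = obj.modality
        signal = obj.signal
        names = list(obj.channel_names)
        toggle_ms = None
    else:
        raise FormatError(f"cannot write object of type {type(obj).__name__}")

    t = np.arange(signal.shape[0]) / obj.sample_rate
    df = pd.DataFrame({"time_s": t})
    for i, name in enumerate(names):
        df[name] = signal[:, i]
    if modality == "lmg-mux":
        df["led_state"] = obj.led_state
    df["trigger"] = obj.trigger
    df["repetition"] = obj.repetition_id
    if force is not None:
        if force.shape[0] != signal.shape[0]:
            raise FormatError("force track length must match the session")
        df["force"] = force

    meta = {
        "modality": modality,
        "sample_rate": obj.sample_rate,
        "subject_id": obj.subject_id,
        "channel_names": names,
        "n_samples": int(signal.shape[0]),
        "has_force": force is not None,
    }
    if toggle_ms is not None:
        meta["toggle_ms"] = toggle_ms
    if extra_meta:
        meta.update(extra_meta)
    meta["provenance"] = _provenance(meta)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_session(path):
    """Read a session CSV + sidecar back into its in-memory form.

    Returns a :class:`MultiplexedLMG`, a :class:`SessionRecording`, or a
    :class:`ForceSession` when a force column is present.  Raises
    :class:`FormatError` on missing columns or a sidecar/grid sample-rate
    mismatch.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "trigger", "repetition"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    fs = float(meta["sample_rate"])
    if len(df) > 1:
        dt = float(np.median(np.diff(df["time_s"].to_numpy())))
        if abs(dt * fs - 1.0) > 1e-6:
            raise FormatError(
                f"sidecar sample_rate {fs} Hz inconsistent with row spacing {dt} s"
            )
    names = meta["channel_names"]
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise FormatError(f"missing channel column(s) {missing}")
    signal = df[names].to_numpy(dtype=float)
    trigger = df["trigger"].to_numpy(dtype="U16")
    rep = df["repetition"].to_numpy(dtype=np.int64)
    modality = meta["modality"]
    if modality == "lmg-mux":
        if "led_state" not in df.columns:
            raise FormatError("multiplexed LMG session lacks a led_state column")
        mux = MultiplexedLMG(
            signal, df["led_state"].to_numpy(dtype="U5"), fs,
            float(meta.get("toggle_ms", 125.0)), trigger, rep,
            meta.get("subject_id", "unknown"),
        )
        if meta.get("has_force") and "force" in df.columns:
            return ForceSession(mux, ForceTrace(df["force"].to_numpy(float), fs))
        return mux
    return SessionRecording(
        signal, trigger, rep, fs, modality,
        meta.get("subject_id", "unknown"), channel_names=tuple(names),
    )
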