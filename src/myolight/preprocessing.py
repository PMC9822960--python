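"""Raw sessions -> balanced, labelled fixed-length windows.

Stages: LED demultiplexing of the time-multiplexed photodiode track into 10
logical channels (5 green + 5 IR), Butterworth bandpass filtering for EMG,
sliding-window extraction (default 200 ms window, 20 ms stride), and
class-count balancing.  LMG windows are consumed raw by the decoders; only
EMG is filtered and feature-extracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .errors import ContractError, FormatError
from .simulate import GREEN, IR, MultiplexedLMG, SessionRecording

log = logging.getLogger(__name__)


@dataclass
class WindowSet:
    """Tensor of fixed-length windows with per-window label and repetition id.

    ``windows`` is ``[N, L, C]`` (window length L in samples, C channels).
    ``targets`` optionally carries a per-window regression target (e.g. the
    grip force at the window's final sample).
    """

    windows: np.ndarray  # [N, L, C]
    labels: np.ndarray  # [N] str
    repetition_ids: np.ndarray  # [N] int
    window_ms: float
    stride_ms: float
    modality: str
    sample_rate: float
    targets: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.windows.shape[0]
        if self.labels.shape[0] != n or self.repetition_ids.shape[0] != n:
            raise ContractError("labels/repetition_ids must match window count")
        if self.targets is not None and self.targets.shape[0] != n:
            raise ContractError("targets must match window count")

    def __len__(self) -> int:
        return self.windows.shape[0]

    def select(self, idx: np.ndarray) -> "WindowSet":
        return replace(
            self,
            windows=self.windows[idx],
            labels=self.labels[idx],
            repetition_ids=self.repetition_ids[idx],
            targets=None if self.targets is None else self.targets[idx],
        )


def demultiplex(
    mux: MultiplexedLMG, method: str = "hold", dtype=np.float64
) -> SessionRecording:
    """Separate the multiplexed photodiode track into per-LED channels.

    Produces 10 logical channels (gr01..gr05, ir01..ir05) on the full sample
    grid.  With ``method="hold"`` (sample-and-hold) each logical channel
    keeps the photodiode value while its LED is lit and carries the last lit
    value forward while the other LED is lit; samples before a channel's
    first lit interval are back-filled.  ``method="cycle_mean"`` instead
    holds the mean of each lit run.
    """
    states = np.unique(mux.led_state)
    bad = set(states) - {GREEN, IR}
    if bad:
        raise FormatError(f"led_state contains invalid values: {sorted(bad)}")
    if method not in ("hold", "cycle_mean"):
        raise ContractError(f"unknown demultiplex method {method!r}")

    t_n, n_mod = mux.samples.shape
    out = np.empty((t_n, 2 * n_mod), dtype=dtype)
    for k, color in enumerate((GREEN, IR)):
        mask = mux.led_state == color
        block = np.where(mask[:, None], mux.samples, np.nan)
        if method == "cycle_mean" and mask.any():
            # replace each lit run by its mean before the hold
            edges = np.flatnonzero(np.diff(mask.astype(np.int8)) != 0) + 1
            for s, e in zip(np.r_[0, edges], np.r_[edges, t_n]):
                if mask[s]:
                    block[s:e] = np.nanmean(block[s:e], axis=0, keepdims=True)
        frame = pd.DataFrame(block).ffill().bfill()
        out[:, k * n_mod : (k + 1) * n_mod] = frame.to_numpy(dtype=dtype)
    names = tuple(f"gr{i + 1:02d}" for i in range(n_mod)) + tuple(
        f"ir{i + 1:02d}" for i in range(n_mod)
    )
    return SessionRecording(
        out,
        mux.trigger,
        mux.repetition_id,
        mux.sample_rate,
        "lmg",
        mux.subject_id,
        channel_names=names,
    )


def butterworth_bandpass(
    x: np.ndarray,
    low_hz: float = 5.0,
    high_hz: float = 500.0,
    order: int = 4,
    sample_rate: float = 1200.0,
    zero_phase: bool = False,
) -> np.ndarray:
    """Causal Butterworth bandpass applied per channel (axis 0).

    A high cutoff at or above Nyquist is clamped to 0.99 x Nyquist with a
    logged warning.  ``zero_phase`` switches to forward-backward filtering
    for offline use.
    """
    if not 0 < low_hz < high_hz:
        raise ContractError("need 0 < low_hz < high_hz")
    if sample_rate <= 2 * low_hz:
        raise ContractError("sample_rate must exceed twice the low cutoff")
    nyq = sample_rate / 2.0
    if high_hz >= nyq:
        clamped = 0.99 * nyq
        log.warning(
            "high cutoff %.6g Hz >= Nyquist %.6g Hz; clamping to %.6g Hz",
            high_hz, nyq, clamped,
        )
        high_hz = clamped
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=sample_rate,
                     output="sos")
    x = np.asarray(x, dtype=float)
    filt = sps.sosfiltfilt if zero_phase else sps.sosfilt
    return filt(sos, x, axis=0)


def _window_label(labels_2d: np.ndarray, policy: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-window label plus keep-mask under the given policy."""
    first = labels_2d[:, :1]
    uniform = (labels_2d == first).all(axis=1)
    if policy == "strict":
        return first[:, 0], uniform
    if policy == "majority":
        out = np.empty(labels_2d.shape[0], dtype=labels_2d.dtype)
        out[uniform] = first[uniform, 0]
        for i in np.flatnonzero(~uniform):
            vals, counts = np.unique(labels_2d[i], return_counts=True)
            out[i] = vals[np.argmax(counts)]
        return out, np.ones(labels_2d.shape[0], dtype=bool)
    raise ContractError(f"unknown label policy {policy!r}")


def slide_windows(
    session: SessionRecording,
    window_ms: float = 200.0,
    stride_ms: float = 20.0,
    label_policy: str = "majority",
    targets: np.ndarray | None = None,
    dtype=np.float32,
) -> WindowSet:
    """Extract overlapping fixed-length windows from a contiguous session.

    The window count is ``floor((T - L) / S) + 1`` for T session samples,
    window length L and stride S (in samples).  Per-window labels follow
    ``label_policy``: ``"majority"`` takes the most frequent trigger label
    inside the window, ``"strict"`` drops windows spanning more than one
    label.  ``targets`` (a per-sample series on the same grid) is reduced to
    the window's final sample — the value a causal estimator would predict.
    """
    if stride_ms <= 0:
        raise ContractError("stride_ms must be positive")
    fs = session.sample_rate
    length = int(round(window_ms * fs / 1000.0))
    stride = int(round(stride_ms * fs / 1000.0))
    t_n = session.n_samples
    if length < 1 or stride < 1:
        raise ContractError("window and stride must span at least one sample")
    if length > t_n:
        log.warning("window (%d samples) longer than session (%d); zero windows",
                    length, t_n)
        empty = np.empty((0, length, session.signal.shape[1]), dtype=dtype)
        return WindowSet(
            empty, np.empty(0, dtype="U16"), np.empty(0, dtype=np.int64),
            window_ms, stride_ms, session.modality, fs,
            targets=None if targets is None else np.empty(0),
        )

    win = sliding_window_view(session.signal, length, axis=0)[::stride]  # [N, C, L]
    win = np.ascontiguousarray(win.transpose(0, 2, 1), dtype=dtype)  # [N, L, C]
    lab2d = sliding_window_view(session.trigger, length)[::stride]
    rep2d = sliding_window_view(session.repetition_id, length)[::stride]
    labels, keep = _window_label(lab2d, label_policy)
    # repetition id: value at the window's final sample (constant within a
    # rest+gesture block, which is the unit blocked CV separates)
    reps = rep2d[:, -1].astype(np.int64)
    tgt = None
    if targets is not None:
        if targets.shape[0] != t_n:
            raise ContractError("targets must be on the session sample grid")
        tgt = sliding_window_view(np.asarray(targets, dtype=float), length)[::stride][:, -1]
    ws = WindowSet(win, labels, reps, window_ms, stride_ms, session.modality, fs,
                   targets=tgt)
    return ws.select(np.flatnonzero(keep)) if not keep.all() else ws


def balance_classes(
    ws: WindowSet, seed: int = 0, expected_labels=None
) -> WindowSet:
    """Down-sample every class uniformly at random to the minimum class count.

    Selection is seeded and the relative window order is preserved; the
    output windows are a sub-multiset of the input.  When
    ``expected_labels`` is given, a listed class with no windows raises a
    :class:`ContractError` naming it.
    """
    if len(ws) == 0:
        raise ContractError("cannot balance an empty window set")
    labels, counts = np.unique(ws.labels, return_counts=True)
    if expected_labels is not None:
        missing = sorted(set(expected_labels) - set(labels))
        if missing:
            raise ContractError(f"no windows for class(es): {missing}")
    n_min = int(counts.min())
    if counts.max() == n_min:
        return ws
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for lab in labels:
        idx = np.flatnonzero(ws.labels == lab)
        keep.append(rng.choice(idx, size=n_min, replace=False))
    return ws.select(np.sort(np.concatenate(keep)))
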