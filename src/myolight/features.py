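"""Time-domain sEMG features, computed per window and per channel.

The eight classical features, in the Phinyomark convention:

- RMS   root mean square, ``sqrt(mean(x^2))``
- WL    waveform length, ``sum |x[i+1] - x[i]|``
- ZC    zero crossings: sign changes whose step also exceeds ``eps_zc``
- MAV   mean absolute value
- iEMG  integrated EMG, ``sum |x|`` (= L * MAV)
- WAMP  Willison amplitude: steps ``|x[i+1] - x[i]| >= eps_wamp``
- VAR   sample variance about the window mean (ddof=1)
- LOG   log detector, ``exp(mean(log(|x| + delta_log)))``

EMG-driven decoders consume the resulting table; LMG windows bypass this
stage and are fed to the models raw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .preprocessing import WindowSet

log = logging.getLogger(__name__)

FEATURE_NAMES = ("rms", "wl", "zc", "mav", "iemg", "wamp", "var", "log")


@dataclass(frozen=True)
class Thresholds:
    """Comparator thresholds for the counting features and the log offset.

    ``eps_zc`` (zero-crossing hysteresis) defaults to 0; ``eps_wamp`` to
    0.005 signal units, a common sEMG choice; ``delta_log`` keeps the log
    detector finite on silent windows.
    """

    eps_zc: float = 0.0
    eps_wamp: float = 0.005
    delta_log: float = 1e-12


def _features_2d(x: np.ndarray, thr: Thresholds) -> np.ndarray:
    """Feature block for a stack of windows ``[N, L] -> [N, 8]``."""
    n, length = x.shape
    if length < 2:
        raise ContractError("windows must have at least 2 samples")
    absx = np.abs(x)
    diffs = np.diff(x, axis=1)
    absd = np.abs(diffs)
    mav = absx.mean(axis=1)
    out = np.empty((n, len(FEATURE_NAMES)))
    out[:, 0] = np.sqrt(np.mean(x * x, axis=1))  # RMS
    out[:, 1] = absd.sum(axis=1)  # WL
    out[:, 2] = np.sum((x[:, :-1] * x[:, 1:] < 0) & (absd >= thr.eps_zc), axis=1)  # ZC
    out[:, 3] = mav
    out[:, 4] = absx.sum(axis=1)  # iEMG
    out[:, 5] = np.sum(absd >= thr.eps_wamp, axis=1)  # WAMP
    out[:, 6] = x.var(axis=1, ddof=1)  # VAR
    out[:, 7] = np.exp(np.mean(np.log(absx + thr.delta_log), axis=1))  # LOG
    return out


def compute_window_features(
    x: np.ndarray, thresholds: Thresholds = Thresholds()
) -> np.ndarray:
    """The 8-feature vector of a single-channel window (ordered as FEATURE_NAMES)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] < 2:
        raise ContractError("need a 1-D window with at least 2 samples")
    return _features_2d(x[None, :], thresholds)[0]


@dataclass
class FeatureTable:
    """``[N x (C*8)]`` feature matrix with per-window labels carried through."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    labels: np.ndarray
    repetition_ids: np.ndarray
    thresholds: Thresholds

    def __len__(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "label", self.labels)
        df.insert(1, "repetition", self.repetition_ids)
        return df


def feature_table(
    ws: WindowSet, thresholds: Thresholds = Thresholds()
) -> FeatureTable:
    """Per-channel features of every window, channels concatenated left-to-right.

    Row ``n`` is the concatenation over channels of the 8-feature vector of
    window ``n``.  Windows containing non-finite samples are dropped with a
    logged count.
    """
    n, length, n_ch = ws.windows.shape
    names = tuple(
        f"ch{c + 1:02d}_{f}" for c in range(n_ch) for f in FEATURE_NAMES
    )
    if n == 0:
        return FeatureTable(
            np.empty((0, 8 * n_ch)), names, ws.labels.copy(),
            ws.repetition_ids.copy(), thresholds,
        )
    finite = np.isfinite(ws.windows).all(axis=(1, 2))
    if not finite.all():
        log.warning("dropping %d window(s) with non-finite samples",
                    int((~finite).sum()))
    w = np.asarray(ws.windows[finite], dtype=float)
    blocks = [_features_2d(w[:, :, c], thresholds) for c in range(n_ch)]
    return FeatureTable(
        np.concatenate(blocks, axis=1), names,
        ws.labels[finite], ws.repetition_ids[finite], thresholds,
    )
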