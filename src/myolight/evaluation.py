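"""Cross-validated evaluation and the study's metrics.

Metrics
-------
- **Performance index** ``I = |S̄g - S̄r| / (Φv · Rp)`` — a sensor figure of
  merit: the rest-to-gesture signal deflection normalized by LED luminous
  intensity and photodiode responsivity, making modules with different LEDs
  comparable.
- **NMSE (%)** ``100 (1 - ||x_r - x_p||² / ||x_r - mean(x_r)||²)`` — a
  trajectory fit score: 100 means the prediction equals the reference,
  0 means no better than predicting the reference mean.
- **Pearson r** between predicted and true force trajectories.
- Classification **accuracy** per held-out fold.

Cross-validation is repetition-blocked by default: folds separate whole
movement repetitions, so 90 %-overlapping windows never straddle train and
test.  Window-random folds are available for comparison but are optimistic
under this windowing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .decoders import ModelSpec, TrainConfig, build_model
from .errors import ConfigError, ContractError, DomainError


@dataclass(frozen=True)
class SensorBench:
    """Bench measurement of one LMG module for the performance index.

    ``luminosity`` is the LED luminous intensity (datasheet units) and
    ``responsivity`` the photodiode responsivity at the LED's dominant
    wavelength.
    """

    s_gesture_mean: float
    s_rest_mean: float
    luminosity: float
    responsivity: float

    def __post_init__(self) -> None:
        if self.luminosity <= 0 or self.responsivity <= 0:
            raise DomainError("luminosity and responsivity must be positive")


def performance_index(b: SensorBench) -> float:
    """``|S̄g - S̄r| / (Φv · Rp)`` (unitless)."""
    denom = b.luminosity * b.responsivity
    if denom == 0:  # pragma: no cover - excluded by the constructor
        raise DomainError("luminosity * responsivity must be nonzero")
    return abs(b.s_gesture_mean - b.s_rest_mean) / denom


def nmse_percent(x_ref: np.ndarray, x_pred: np.ndarray) -> float:
    """Percentage normalized mean square error between two trajectories.

    100 iff the trajectories are identical; 0 for a constant prediction at
    the reference mean; can be negative for worse-than-mean predictions.
    """
    x_ref = np.asarray(x_ref, dtype=float)
    x_pred = np.asarray(x_pred, dtype=float)
    if x_ref.shape != x_pred.shape:
        raise ContractError("trajectories must have equal length")
    denom = float(np.sum((x_ref - x_ref.mean()) ** 2))
    if denom == 0:
        raise DomainError("reference trajectory is constant")
    err = float(np.sum((x_ref - x_pred) ** 2))
    return 100.0 * (1.0 - err / denom)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ContractError("need equal-length series with >= 2 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined for constant input")
    return float(spstats.pearsonr(x, y).statistic)


def anova_one_way(group_a, group_b) -> tuple[float, float]:
    """Classical one-way ANOVA F and p for two groups.

    Degenerate convention: zero within-group variance with equal means gives
    ``(0.0, 1.0)``; zero within-group variance with different means gives
    ``(inf, 0.0)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ContractError("each group needs at least 2 values")
    n = a.size + b.size
    grand = (a.sum() + b.sum()) / n
    ssb = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ssw = float(((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
    df_b, df_w = 1, n - 2
    if ssw == 0.0:
        return (0.0, 1.0) if ssb == 0.0 else (float("inf"), 0.0)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(spstats.f.sf(f, df_b, df_w))
    return float(f), p


@dataclass
class CVReport:
    """Per-fold metric values with mean/std aggregates."""

    per_fold_metrics: dict[str, np.ndarray]
    k: int
    grouping: str

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigError("cross-validation needs k >= 2")
        for name, vals in self.per_fold_metrics.items():
            if len(vals) != self.k:
                raise ContractError(f"metric {name!r} has != k fold values")

    @property
    def metric_names(self) -> tuple[str, ...]:
        return tuple(self.per_fold_metrics)

    def mean(self, metric: str) -> float:
        return float(np.mean(self.per_fold_metrics[metric]))

    def std(self, metric: str) -> float:
        return float(np.std(self.per_fold_metrics[metric], ddof=1))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": list(self.metric_names),
                "mean": [self.mean(m) for m in self.metric_names],
                "std": [self.std(m) for m in self.metric_names],
                "k": self.k,
                "grouping": self.grouping,
            }
        )


def _repetition_folds(reps: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    uniq = np.unique(reps)
    if uniq.size < k:
        raise ConfigError(
            f"{uniq.size} repetitions cannot form {k} repetition-blocked folds"
        )
    order = np.random.default_rng(seed).permutation(uniq)
    return [np.sort(part) for part in np.array_split(order, k)]


def _check_partition(test_sets: list[np.ndarray], n: int) -> None:
    # leakage guard: test windows are disjoint and exhaustive
    allidx = np.concatenate(test_sets)
    if allidx.size != n or np.unique(allidx).size != n:
        raise ContractError("fold test sets do not partition the windows")


def crossval_classification(
    X,
    labels: np.ndarray,
    repetition_ids: np.ndarray,
    spec: ModelSpec | None,
    k: int = 5,
    seed: int = 0,
    cfg: TrainConfig | None = None,
    grouping: str = "repetition",
    model_factory=None,
) -> CVReport:
    """k-fold cross-validated accuracy.

    With ``grouping="repetition"`` (default) the folds partition whole
    repetitions into k near-equal groups; ``"window"`` shuffles windows
    directly.  ``model_factory`` overrides ``spec`` (used for stubs in
    tests); each fold gets a freshly built model.
    """
    labels = np.asarray(labels)
    reps = np.asarray(repetition_ids)
    n = labels.shape[0]
    if grouping == "repetition":
        fold_reps = _repetition_folds(reps, k, seed)
        test_sets = [np.flatnonzero(np.isin(reps, fr)) for fr in fold_reps]
    elif grouping == "window":
        order = np.random.default_rng(seed).permutation(n)
        test_sets = [np.sort(part) for part in np.array_split(order, k)]
    else:
        raise ConfigError(f"unknown grouping {grouping!r}")
    _check_partition(test_sets, n)

    accs = []
    from .decoders import _as_array  # local import to keep module surface clean

    x = _as_array(X)
    for i, test in enumerate(test_sets):
        if test.size == 0:
            raise ConfigError(f"fold {i} has an empty test set")
        train_idx = np.setdiff1d(np.arange(n), test, assume_unique=False)
        if np.intersect1d(reps[train_idx], reps[test]).size and grouping == "repetition":
            raise ContractError("repetition leaked between train and test")
        if model_factory is not None:
            model = model_factory()
            model.fit(x[train_idx], labels[train_idx])
        else:
            model = build_model(replace(spec, seed=spec.seed + i))
            model.fit(x[train_idx], labels[train_idx], cfg or TrainConfig(seed=seed))
        pred = np.asarray(model.predict(x[test]))
        accs.append(float(np.mean(pred == labels[test])))
    return CVReport({"accuracy": np.asarray(accs)}, k=k, grouping=grouping)


def crossval_regression(
    X,
    targets: np.ndarray,
    repetition_ids: np.ndarray,
    spec: ModelSpec | None,
    folds: int = 10,
    seed: int = 0,
    cfg: TrainConfig | None = None,
    model_factory=None,
) -> CVReport:
    """Leave-one-repetition-out regression CV (one repetition tested per fold).

    Requires exactly ``folds`` distinct repetitions.  Per fold, Pearson r
    and NMSE (%) are computed between the predicted and true force over the
    held-out repetition's concatenated (time-ordered) trajectory.
    """
    targets = np.asarray(targets, dtype=float)
    reps = np.asarray(repetition_ids)
    uniq = np.unique(reps)
    if uniq.size != folds:
        raise ConfigError(
            f"regression CV needs exactly {folds} repetitions, got {uniq.size}"
        )
    from .decoders import _as_array

    x = _as_array(X)
    n = targets.shape[0]
    test_sets = [np.flatnonzero(reps == r) for r in uniq]
    _check_partition(test_sets, n)
    nmse_vals, r_vals = [], []
    for i, test in enumerate(test_sets):
        train_idx = np.flatnonzero(reps != uniq[i])
        if model_factory is not None:
            model = model_factory()
            model.fit(x[train_idx], targets[train_idx])
        else:
            model = build_model(replace(spec, seed=spec.seed + i))
            model.fit(x[train_idx], targets[train_idx], cfg or TrainConfig(seed=seed))
        pred = np.asarray(model.predict(x[test]), dtype=float)
        nmse_vals.append(nmse_percent(targets[test], pred))
        try:
            r_vals.append(pearson_r(targets[test], pred))
        except DomainError:  # constant prediction: correlation undefined
            r_vals.append(np.nan)
    return CVReport(
        {"nmse": np.asarray(nmse_vals), "pearson_r": np.asarray(r_vals)},
        k=folds,
        grouping="repetition",
    )


@dataclass
class ResultsTable:
    """Per-subject x column metric grid with AVG/MAX aggregate rows.

    ``table`` holds one row per subject; ``avg_row`` is the arithmetic mean
    of the subject rows, ``max_row`` the per-column maximum, and ``best``
    flags the better HMI per subject where both an LMG and an EMG column
    exist for a model.
    """

    table: pd.DataFrame
    avg_row: pd.Series
    max_row: pd.Series
    anova: tuple[float, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.loc["AVG"] = self.avg_row
        out.loc["MAX"] = self.max_row
        return out


def aggregate_results(per_subject: pd.DataFrame, value: str = "mean") -> ResultsTable:
    """Aggregate tidy per-subject results into a study-style table.

    ``per_subject`` is tidy with columns ``subject``, ``model``, ``hmi``
    (or ``metric``), and the value column; missing cells raise a
    :class:`ContractError` naming the cell.  When both LMG and EMG columns
    are present, a two-group one-way ANOVA over all per-subject x model
    means per HMI is attached.
    """
    key_cols = [c for c in ("model", "hmi", "metric") if c in per_subject.columns]
    if "subject" not in per_subject.columns or not key_cols or value not in per_subject:
        raise ContractError("need tidy columns: subject, model[, hmi|metric], value")
    wide = per_subject.pivot_table(
        index="subject", columns=key_cols, values=value, aggfunc="first"
    )
    if wide.isna().any().any():
        missing = [
            (str(idx), col) for col in wide.columns
            for idx in wide.index[wide[col].isna()]
        ]
        raise ContractError(f"missing result cell(s): {missing[:5]}")
    anova = None
    if "hmi" in key_cols:
        hmi_level = key_cols.index("hmi")
        hmis = wide.columns.get_level_values(hmi_level) if len(key_cols) > 1 \
            else wide.columns
        groups = {}
        for h in np.unique(np.asarray(hmis)):
            sel = wide.loc[:, np.asarray(hmis) == h]
            groups[h] = sel.to_numpy().ravel()
        if len(groups) == 2:
            anova = anova_one_way(*groups.values())
    return ResultsTable(
        table=wide,
        avg_row=wide.mean(axis=0),
        max_row=wide.max(axis=0),
        anova=anova,
    )
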