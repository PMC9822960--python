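import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as spstats

from myolight import published
from myolight.errors import ConfigError, ContractError, DomainError
from myolight.evaluation import (
    CVReport,
    SensorBench,
    aggregate_results,
    anova_one_way,
    crossval_classification,
    crossval_regression,
    nmse_percent,
    pearson_r,
    performance_index,
)


class TestPerformanceIndex:
    def test_equal_means_give_zero(self):
        assert performance_index(SensorBench(3.0, 3.0, 2.0, 0.4)) == 0.0

    def test_worked_example(self):
        assert performance_index(SensorBench(2.0, 1.0, 4.0, 0.5)) == 0.5

    def test_symmetric_in_gesture_and_rest(self):
        a = performance_index(SensorBench(2.0, 1.0, 4.0, 0.5))
        b = performance_index(SensorBench(1.0, 2.0, 4.0, 0.5))
        assert a == b

    def test_offset_invariant_and_inverse_scaling(self):
        base = performance_index(SensorBench(2.0, 1.0, 4.0, 0.5))
        shifted = performance_index(SensorBench(12.0, 11.0, 4.0, 0.5))
        assert shifted == base
        doubled = performance_index(SensorBench(2.0, 1.0, 8.0, 0.5))
        assert doubled == base / 2

    def test_nonpositive_optics_rejected(self):
        with pytest.raises(DomainError):
            SensorBench(2.0, 1.0, 0.0, 0.5)


class TestNMSE:
    def test_identity_scores_100(self):
        x = np.linspace(0.0, 1.0, 100)
        assert nmse_percent(x, x.copy()) == 100.0

    def test_mean_predictor_scores_0(self):
        x = np.linspace(0.0, 1.0, 100)
        assert nmse_percent(x, np.full_like(x, x.mean())) == pytest.approx(0.0)

    def test_worked_example_scores_50(self):
        assert nmse_percent([1, 2, 3], [1, 2, 4]) == pytest.approx(50.0)

    def test_constant_reference_rejected(self):
        with pytest.raises(DomainError):
            nmse_percent(np.ones(10), np.zeros(10))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            nmse_percent(np.arange(5), np.arange(4))

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(seed=st.integers(0, 10_000))
    def test_never_exceeds_100_and_100_iff_exact(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        p = rng.normal(size=30)
        v = nmse_percent(x, p)
        assert v <= 100.0
        assert (v == 100.0) == bool(np.array_equal(x, p))


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        x = np.arange(10.0)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson_r([1, 2, 3], [1, 2, 2]) == pytest.approx(np.sqrt(3) / 2)

    def test_constant_input_rejected(self):
        with pytest.raises(DomainError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestAnova:
    def test_identical_groups(self):
        f, p = anova_one_way([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert f == 0.0 and p == 1.0

    def test_hand_anova_table(self):
        f, p = anova_one_way([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert f == pytest.approx(1.5)

    def test_degenerate_zero_variance_convention(self):
        assert anova_one_way([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
        f, p = anova_one_way([2.0, 2.0], [3.0, 3.0])
        assert np.isinf(f) and p == 0.0

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(seed=st.integers(0, 10_000), na=st.integers(2, 12), nb=st.integers(2, 12))
    def test_matches_scipy_sum_of_squares_oracle(self, seed, na, nb):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=na), 0.5 + rng.normal(size=nb)
        f, p = anova_one_way(a, b)
        ref = spstats.f_oneway(a, b)
        assert f == pytest.approx(ref.statistic, abs=1e-10, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10, rel=1e-10)


class MajorityStub:
    def fit(self, x, y):
        vals, counts = np.unique(y, return_counts=True)
        self.guess = vals[np.argmax(counts)]
        return self

    def predict(self, x):
        return np.full(x.shape[0], self.guess, dtype="U16")


class FirstColumnStub:
    """Reads the label (or target) planted in each row's first element."""

    def fit(self, x, y):
        self.classes_ = np.unique(y)
        return self

    def predict(self, x):
        flat = x.reshape(x.shape[0], -1)[:, 0]
        if self.classes_.dtype.kind in "UM":
            return self.classes_[flat.astype(int)]
        return flat.astype(float)


class MeanStub:
    def fit(self, x, y):
        self.mean = float(np.mean(y))
        return self

    def predict(self, x):
        return np.full(x.shape[0], self.mean)


def balanced_windows(n_reps=6, per_rep=20, n_classes=5):
    labels, reps, rows = [], [], []
    names = np.array([f"g{i}" for i in range(n_classes)])
    for r in range(1, n_reps + 1):
        for c in range(n_classes):
            for _ in range(per_rep):
                rows.append([c, r])
                labels.append(names[c])
                reps.append(r)
    x = np.asarray(rows, dtype=float)
    return x, np.asarray(labels, dtype="U16"), np.asarray(reps)


class TestCrossvalClassification:
    def test_majority_stub_scores_chance_on_balanced_data(self):
        x, y, reps = balanced_windows()
        rep = crossval_classification(x, y, reps, None, k=5, seed=0,
                                      model_factory=MajorityStub)
        assert rep.mean("accuracy") == pytest.approx(0.2, abs=0.01)

    def test_oracle_stub_scores_one_with_zero_std(self):
        x, y, reps = balanced_windows()
        rep = crossval_classification(x, y, reps, None, k=5, seed=0,
                                      model_factory=FirstColumnStub)
        assert rep.mean("accuracy") == 1.0 and rep.std("accuracy") == 0.0

    def test_fold_repetition_counts_differ_by_at_most_one(self):
        from myolight.evaluation import _repetition_folds

        folds = _repetition_folds(np.arange(1, 12), 5, seed=3)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        assert sorted(np.concatenate(folds)) == list(range(1, 12))

    def test_each_window_tested_exactly_once(self):
        x, y, reps = balanced_windows()
        seen = []

        class Recorder(FirstColumnStub):
            def predict(self, z):
                seen.append(z[:, 1].astype(int))
                return super().predict(z)

        crossval_classification(x, y, reps, None, k=5, seed=0,
                                model_factory=Recorder)
        tested_reps = np.concatenate([np.unique(s) for s in seen])
        assert sorted(tested_reps) == [1, 2, 3, 4, 5, 6]
        assert len(np.concatenate(seen)) == len(y)

    def test_too_few_repetitions_rejected(self):
        x, y, reps = balanced_windows(n_reps=3)
        with pytest.raises(ConfigError):
            crossval_classification(x, y, reps, None, k=5,
                                    model_factory=MajorityStub)

    def test_window_random_grouping_partitions_windows(self):
        x, y, reps = balanced_windows(n_reps=2)
        rep = crossval_classification(x, y, reps, None, k=4, seed=1,
                                      grouping="window",
                                      model_factory=FirstColumnStub)
        assert rep.mean("accuracy") == 1.0


def ramp_windows(n_reps=10, per_rep=30):
    """Per-repetition identical triangular force targets planted in column 0."""
    tgt = np.concatenate([np.linspace(0, 0.5, per_rep // 2),
                          np.linspace(0.5, 0, per_rep - per_rep // 2)])
    x = np.tile(tgt, n_reps)[:, None]
    reps = np.repeat(np.arange(1, n_reps + 1), per_rep)
    return x, np.tile(tgt, n_reps), reps


class TestCrossvalRegression:
    def test_identity_oracle_scores_nmse_100_r_1(self):
        x, t, reps = ramp_windows()
        rep = crossval_regression(x, t, reps, None, folds=10,
                                  model_factory=FirstColumnStub)
        assert np.all(rep.per_fold_metrics["nmse"] == 100.0)
        np.testing.assert_allclose(rep.per_fold_metrics["pearson_r"], 1.0)

    def test_mean_predictor_scores_nmse_0(self):
        x, t, reps = ramp_windows()
        rep = crossval_regression(x, t, reps, None, folds=10,
                                  model_factory=MeanStub)
        np.testing.assert_allclose(rep.per_fold_metrics["nmse"], 0.0, atol=1e-9)

    def test_repetition_count_must_equal_folds(self):
        x, t, reps = ramp_windows(n_reps=8)
        with pytest.raises(ConfigError):
            crossval_regression(x, t, reps, None, folds=10,
                                model_factory=MeanStub)

    def test_cv_report_requires_k_of_2(self):
        with pytest.raises(ConfigError):
            CVReport({"accuracy": np.array([1.0])}, k=1, grouping="repetition")


class TestAggregation:
    def test_reproduces_printed_gesture_aggregates(self):
        table = aggregate_results(published.gesture_results())
        assert round(table.avg_row[("tmcvit", "lmg")], 2) == 98.24
        assert table.max_row[("tmcvit", "lmg")] == 99.11
        assert round(table.avg_row[("rf", "lmg")], 2) == 96.97
        assert round(table.avg_row[("cnn", "emg")], 2) == 97.18

    def test_reproduces_printed_force_aggregates(self):
        table = aggregate_results(published.force_results())
        assert round(table.avg_row[("tmcvit", "acc")], 2) == 90.46
        assert table.max_row[("tmcvit", "acc")] == 98.09
        assert round(table.avg_row[("tmcvit", "corr")], 2) == 95.93
        corr_cols = [c for c in table.max_row.index if c[1] == "corr"]
        assert max(table.max_row[c] for c in corr_cols) == 99.15

    def test_anova_of_lmg_vs_emg_means_matches_printed_p(self):
        table = aggregate_results(published.gesture_results())
        f, p = table.anova
        assert round(p, 4) == 0.0381
        assert p < 0.05

    def test_single_subject_avg_equals_row(self):
        df = published.gesture_results()
        one = df[df.subject == 3]
        table = aggregate_results(one)
        np.testing.assert_allclose(table.avg_row.to_numpy(),
                                   table.table.iloc[0].to_numpy())

    def test_missing_cell_is_named(self):
        df = published.gesture_results()
        df = df[~((df.subject == 4) & (df.model == "cnn") & (df.hmi == "lmg"))]
        with pytest.raises(ContractError, match="missing"):
            aggregate_results(df)
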