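"""AUC, nested-CV harness geometry, ranking, CIs and leakage safety."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from ptpdomics.balance import ResampleSpec
from ptpdomics.evaluate import (
    CVResult,
    LogitBoostClassifier,
    auc,
    nested_cv_evaluate,
    rank_models,
    single_feature_model,
    summarize,
)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_hand_counted_pairs(self):
        # concordant 3, discordant 1 of 4 pairs -> 0.75
        assert auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == pytest.approx(0.5)

    def test_matches_sklearn_on_random_scores(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(30), 1)  # coarse scores force ties
            assert auc(s, y) == pytest.approx(roc_auc_score(y, s))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestLogitBoost:
    def test_learns_separable_data(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((120, 4))
        y = (x[:, 0] + 0.5 * x[:, 1] > 0).astype(int)
        model = LogitBoostClassifier(n_estimators=30).fit(x, y)
        assert auc(model.predict_proba(x)[:, 1], y) > 0.9

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        model = LogitBoostClassifier(n_estimators=11)
        cloned = clone(model)
        assert cloned.get_params()["n_estimators"] == 11


def planted_table(n=110, p=6, beta=2.0, seed=0, n_events=24):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, p))
    u = beta * x[:, 0] + rng.logistic(size=n)
    y = np.zeros(n, dtype=int)
    y[np.argsort(-u)[:n_events]] = 1
    return pd.DataFrame(x, columns=[f"f{j}" for j in range(p)]), y


FAST_MODELS = {"logistic": LogisticRegression(max_iter=1000)}
FAST_GRIDS = {"logistic": [{}]}


class TestNestedCV:
    def test_fold_geometry_110_cases(self):
        """n=110 gives outer 88:22 splits and modal inner 70:18 splits."""
        table, y = planted_table()
        cv = nested_cv_evaluate(
            table, y, models=FAST_MODELS, grids=FAST_GRIDS, n_iter=1, seed=0, resample=None
        )
        assert set(cv.records["n_train"]) == {88}
        assert set(cv.records["n_test"]) == {22}
        from sklearn.model_selection import StratifiedKFold

        inner_sizes = []
        outer = StratifiedKFold(5, shuffle=True, random_state=0)
        tr, _ = next(iter(outer.split(table, y)))
        inner = StratifiedKFold(5, shuffle=True, random_state=1)
        for a, b in inner.split(table.iloc[tr], y[tr]):
            inner_sizes.append((len(a), len(b)))
        modal = max(set(inner_sizes), key=inner_sizes.count)
        assert modal == (70, 18)

    def test_outer_folds_partition_cohort(self):
        """Each iteration's test folds cover every case exactly once."""
        from sklearn.model_selection import StratifiedKFold

        table, y = planted_table(n=60, n_events=14)
        seen = np.zeros(60, dtype=int)
        for _, te in StratifiedKFold(5, shuffle=True, random_state=3).split(table, y):
            seen[te] += 1
        assert np.all(seen == 1)

    def test_signal_detected_and_reproducible(self):
        table, y = planted_table(beta=3.0)
        cv1 = nested_cv_evaluate(
            table, y, models=FAST_MODELS, grids=FAST_GRIDS, n_iter=3, seed=5,
            resample=ResampleSpec(),
        )
        assert cv1.mean_auc() > 0.65
        cv2 = nested_cv_evaluate(
            table, y, models=FAST_MODELS, grids=FAST_GRIDS, n_iter=3, seed=5,
            resample=ResampleSpec(),
        )
        pd.testing.assert_frame_equal(cv1.records, cv2.records)

    def test_no_leakage_from_test_only_label_copy(self):
        """A column that equals the label on one third of rows (and noise
        elsewhere) must not inflate AUC when selection runs inside the
        harness: a leaky harness would select it using test rows."""
        rng = np.random.default_rng(7)
        n = 90
        y = (rng.random(n) < 0.3).astype(int)
        while len(np.unique(y)) < 2:
            y = (rng.random(n) < 0.3).astype(int)
        table = pd.DataFrame(rng.standard_normal((n, 10)), columns=[f"f{j}" for j in range(10)])
        leak = rng.standard_normal(n)
        mask = rng.random(n) < 0.33
        leak[mask] = y[mask] * 10.0  # post-hoc information on a subset
        table["leak"] = leak

        def top2_by_train_corr(tab, labels):
            x = tab.to_numpy()
            x = (x - x.mean(0)) / (x.std(0) + 1e-12)
            r = np.abs(x.T @ (labels - labels.mean()))
            return [tab.columns[i] for i in np.argsort(-r)[:2]]

        cv = nested_cv_evaluate(
            table, y, models=FAST_MODELS, grids=FAST_GRIDS, n_iter=4, seed=2,
            resample=None, selector=top2_by_train_corr,
        )
        # the leak column is partially informative on training rows too, so
        # allow modest signal, but not the near-perfect AUC of true leakage
        assert cv.mean_auc() < 0.75


class TestAggregation:
    def make_cv(self, aucs_by_model):
        rows = []
        for model, aucs in aucs_by_model.items():
            for i, a in enumerate(aucs):
                rows.append(
                    {"iteration": 1 + i // 5, "fold": 1 + i % 5, "model": model,
                     "feature_set": "s", "auc": a}
                )
        return CVResult(records=pd.DataFrame(rows))

    def test_rank_ordering(self):
        cv = self.make_cv({"a": [0.8] * 5, "b": [0.7] * 5, "c": [0.6] * 5, "d": [0.5] * 5})
        _, mean_ranks = rank_models(cv)
        assert mean_ranks["a"] == 1.0 and mean_ranks["d"] == 4.0

    def test_tied_models_share_average_rank(self):
        cv = self.make_cv({"a": [0.8] * 5, "b": [0.8] * 5, "c": [0.5] * 5})
        df, mean_ranks = rank_models(cv)
        assert mean_ranks["a"] == mean_ranks["b"] == 1.5
        assert mean_ranks["c"] == 3.0

    def test_summary_t_interval_matches_reference(self):
        rng = np.random.default_rng(4)
        aucs = 0.7 + 0.05 * rng.standard_normal(25)
        cv = self.make_cv({"m": list(aucs)})
        row = summarize(cv).iloc[0]
        half = stats.t.ppf(0.975, 24) * aucs.std(ddof=1) / np.sqrt(25)
        assert row["mean_auc"] == pytest.approx(aucs.mean())
        assert row["ci_high"] - row["mean_auc"] == pytest.approx(half)

    def test_constant_auc_zero_width_ci(self):
        cv = self.make_cv({"m": [0.66] * 10})
        row = summarize(cv).iloc[0]
        assert row["ci_low"] == row["ci_high"] == pytest.approx(0.66)


class TestSingleFeature:
    def test_label_copy_reaches_high_auc(self):
        rng = np.random.default_rng(5)
        y = (rng.random(100) < 0.3).astype(int)
        feature = pd.Series(y + 0.01 * rng.standard_normal(100), name="copy")
        cv = single_feature_model(feature, y, n_iter=2, seed=1)
        assert cv.mean_auc() > 0.95

    def test_independent_feature_near_chance(self):
        rng = np.random.default_rng(6)
        y = (rng.random(120) < 0.3).astype(int)
        feature = pd.Series(rng.standard_normal(120), name="noise")
        cv = single_feature_model(feature, y, n_iter=5, seed=2)
        assert 0.38 <= cv.mean_auc() <= 0.62

    def test_binary_feature_matches_contingency_arithmetic(self):
        """For a binary score, AUC = P(score1 > score0) + 0.5 P(tie),
        computable from the 2x2 table."""
        y = np.array([1] * 10 + [0] * 30)
        f = np.array([1] * 7 + [0] * 3 + [1] * 6 + [0] * 24)
        # concordant: pos with 1 vs neg with 0 => 7*24; ties: 7*6 + 3*24
        expect = (7 * 24 + 0.5 * (7 * 6 + 3 * 24)) / (10 * 30)
        assert auc(f, y) == pytest.approx(expect)
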