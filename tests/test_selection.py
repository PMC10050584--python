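"""Pearson filter, Boruta and bootstrap frequency ranking."""

import numpy as np
import pandas as pd
import pytest

from ptpdomics.selection import boruta_run, bootstrap_select, pearson_filter


def make_table(n=60, p=10, seed=0, informative=0, beta=3.0):
    """Noise features; the first ``informative`` columns shift with labels."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.35).astype(int)
    while len(np.unique(y)) < 2:
        y = (rng.random(n) < 0.35).astype(int)
    x = rng.standard_normal((n, p))
    for j in range(informative):
        x[:, j] += beta * y
    cols = [f"f{j:02d}" for j in range(p)]
    return pd.DataFrame(x, columns=cols), y


class TestPearsonFilter:
    def test_identical_columns_one_removed(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(50)
        table = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.standard_normal(50)})
        out = pearson_filter(table, 0.7)
        assert out.shape[1] == 2
        assert "c" in out.columns
        assert ("a" in out.columns) != ("b" in out.columns)

    def test_independent_noise_retained(self):
        table, _ = make_table(n=200, p=12, seed=2)
        out = pearson_filter(table, 0.7)
        assert out.shape[1] == 12

    def test_hand_worked_three_feature_example(self):
        """A correlates above the cutoff with both B and C, while B-C are
        weakly correlated: A has the largest mean absolute correlation
        and is dropped; B and C stay."""
        target = np.array([[1.0, 0.85, 0.75], [0.85, 1.0, 0.35], [0.75, 0.35, 1.0]])
        rng = np.random.default_rng(3)
        raw = rng.standard_normal((500, 3))
        # empirically whiten, then colour to the exact target correlation
        raw = raw - raw.mean(0)
        u, s, vt = np.linalg.svd(raw, full_matrices=False)
        white = u @ vt * np.sqrt(len(raw))
        data = white @ np.linalg.cholesky(target).T
        table = pd.DataFrame(data, columns=["A", "B", "C"])
        corr = table.corr().abs()
        assert corr.loc["A", "B"] == pytest.approx(0.85, abs=0.01)
        assert corr.loc["A", "C"] == pytest.approx(0.75, abs=0.01)
        out = pearson_filter(table, 0.7)
        assert list(out.columns) == ["B", "C"]

    def test_constant_column_retained(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(
            {"const": np.ones(30), "x": rng.standard_normal(30), "y": rng.standard_normal(30)}
        )
        out = pearson_filter(table)
        assert "const" in out.columns

    def test_invariant_to_row_and_column_order(self):
        table, _ = make_table(n=80, p=8, seed=5)
        table["dup"] = table["f00"] * 0.95 + 0.05 * np.random.default_rng(0).standard_normal(80)
        base = set(pearson_filter(table).columns)
        shuffled_rows = table.sample(frac=1.0, random_state=1)
        assert set(pearson_filter(shuffled_rows).columns) == base
        shuffled_cols = table[list(reversed(table.columns))]
        assert set(pearson_filter(shuffled_cols).columns) == base


class TestBoruta:
    def test_label_copy_feature_confirmed(self):
        """A feature equal to the label plus small noise is confirmed in
        at least 9 of 10 seeded runs among 20 noise features."""
        confirmations = 0
        for seed in range(10):
            table, y = make_table(n=100, p=21, seed=seed)
            table["f00"] = y + 0.01 * np.random.default_rng(seed).standard_normal(len(y))
            status = boruta_run(table, y, seed=seed, max_iter=30)
            status.pop("__importance__")
            if status["f00"] == "confirmed":
                confirmations += 1
        assert confirmations >= 9

    def test_pure_noise_rarely_confirmed(self):
        table, y = make_table(n=100, p=30, seed=7)
        status = boruta_run(table, y, seed=7, max_iter=30)
        status.pop("__importance__")
        confirmed = [f for f, s in status.items() if s == "confirmed"]
        assert len(confirmed) <= 2  # alpha-consistent false-positive count

    def test_deterministic_given_seed(self):
        table, y = make_table(n=80, p=10, seed=8, informative=1)
        a = boruta_run(table, y, seed=123, max_iter=20)
        b = boruta_run(table, y, seed=123, max_iter=20)
        assert a == b

    def test_single_class_rejected(self):
        table, _ = make_table(n=30, p=5, seed=9)
        with pytest.raises(ValueError):
            boruta_run(table, np.zeros(30, dtype=int), seed=0)


class TestBootstrapSelect:
    def test_contract_and_reproducibility(self):
        table, y = make_table(n=60, p=8, seed=10, informative=2)
        rep1 = bootstrap_select(table, y, n_boot=15, seed=3, max_iter=20, n_estimators=50)
        rep2 = bootstrap_select(table, y, n_boot=15, seed=3, max_iter=20, n_estimators=50)
        assert rep1.frequency == rep2.frequency
        assert rep1.final_set == rep2.final_set
        assert all(0 <= v <= 15 for v in rep1.frequency.values())
        assert len(rep1.final_set) == rep1.median_confirmed

    def test_planted_features_recovered(self):
        """Three strong features among 25 noise columns dominate the
        frequency ranking (scaled-down bootstrap count)."""
        table, y = make_table(n=120, p=28, seed=11, informative=3, beta=2.5)
        report = bootstrap_select(table, y, n_boot=25, seed=5, max_iter=25, n_estimators=60)
        top3 = set(report.to_frame().head(3)["feature"])
        assert top3 == {"f00", "f01", "f02"}
        for f in top3:
            assert report.frequency[f] >= 0.8 * 25

    def test_all_noise_median_small(self):
        """With only noise columns the median confirmed count stays small
        and no feature is selected often."""
        table, y = make_table(n=100, p=30, seed=12)
        report = bootstrap_select(table, y, n_boot=15, seed=6, max_iter=20, n_estimators=50)
        assert report.median_confirmed <= 2
        assert max(report.frequency.values()) < 0.5 * 15
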