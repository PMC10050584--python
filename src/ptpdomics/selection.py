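"""Feature reduction: Pearson intercorrelation filter and bootstrapped
Boruta frequency ranking.

Boruta is an all-relevant wrapper: every iteration appends a shuffled
"shadow" copy of every live feature, fits a random forest, and scores a
hit for features whose importance exceeds the best shadow importance.
Accumulated hits are tested against Binomial(trials, 1/2) two-sided at
level ``alpha`` with a Bonferroni adjustment over the tested features
(the convention of the reference R implementation); decisively winning
features are confirmed, decisively losing ones rejected, survivors stay
tentative (counted as not selected).

``bootstrap_select`` repeats (Pearson filter -> Boruta) on stratified
bootstrap resamples and ranks features by how often they were confirmed;
the final set keeps the top ``m`` features where ``m`` is the median
confirmed count over runs (rounded half-up).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

__all__ = ["SelectionReport", "pearson_filter", "boruta_run", "bootstrap_select"]

log = logging.getLogger(__name__)


@dataclass
class SelectionReport:
    """Bootstrap selection frequencies and the final ranked feature set."""

    frequency: dict            # feature -> confirmed count over bootstrap runs
    median_confirmed: int
    final_set: list            # top-m features, descending frequency
    settings: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.frequency.items(), key=lambda kv: (-kv[1], kv[0]))
        df = pd.DataFrame(items, columns=["feature", "frequency"])
        df["rank"] = np.arange(1, len(df) + 1)
        df["in_final_set"] = df["feature"].isin(self.final_set)
        return df


def pearson_filter(table: pd.DataFrame, cutoff: float = 0.7) -> pd.DataFrame:
    """Drop features until no pair has |Pearson r| > cutoff.

    Deterministic rule: while a violating pair exists, drop the feature
    with the largest mean absolute correlation to all remaining features
    (ties toward the lexicographically larger name).  Constant columns
    have undefined r, are treated as uncorrelated and retained.
    """
    if len(table) < 2:
        raise ValueError("pearson_filter needs at least 2 rows")
    cols = sorted(table.columns)
    x = table[cols].to_numpy(dtype=np.float64)
    sd = x.std(axis=0)
    constant = sd == 0
    if constant.any():
        log.info("pearson_filter: %d constant columns retained (r treated as 0)", constant.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.abs(np.nan_to_num(corr, nan=0.0))
    np.fill_diagonal(corr, 0.0)

    alive = np.ones(len(cols), dtype=bool)
    while True:
        sub = corr[np.ix_(alive, alive)]
        if sub.size == 0 or sub.max() <= cutoff:
            break
        idx_alive = np.flatnonzero(alive)
        mean_abs = sub.mean(axis=1)
        # only features participating in a violating pair are candidates
        violators = (sub > cutoff).any(axis=1)
        order = sorted(
            np.flatnonzero(violators),
            key=lambda k: (-mean_abs[k], cols[idx_alive[k]]),
        )
        # ties toward lexicographically larger name: re-sort equal scores
        best = order[0]
        score = mean_abs[best]
        tied = [k for k in order if mean_abs[k] == score]
        drop_local = max(tied, key=lambda k: cols[idx_alive[k]])
        alive[idx_alive[drop_local]] = False
    kept = [c for c, a in zip(cols, alive) if a]
    # preserve the original column order of the input table
    kept_in_order = [c for c in table.columns if c in set(kept)]
    return table[kept_in_order]


def _importances(
    model: RandomForestClassifier,
    x: np.ndarray,
    y: np.ndarray,
    kind: str,
    rng: np.random.Generator,
) -> np.ndarray:
    if kind == "impurity":
        return model.feature_importances_
    if kind == "permutation":
        result = permutation_importance(
            model, x, y, n_repeats=5, random_state=int(rng.integers(2**31 - 1))
        )
        return result.importances_mean
    raise ValueError(f"unknown importance kind {kind!r}")


def boruta_run(
    table: pd.DataFrame,
    labels: np.ndarray,
    alpha: float = 0.01,
    max_iter: int = 100,
    seed: int = 0,
    *,
    n_estimators: int = 100,
    importance: str = "impurity",
    mc_adjust: bool = True,
) -> dict:
    """Boruta shadow-feature selection.

    Returns ``{feature: status}`` with status in {"confirmed",
    "rejected", "tentative"}, plus mean real-feature importances under
    key ``"__importance__"`` (used only for deterministic tie-breaks in
    the bootstrap ranking).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("boruta_run requires both classes present")
    rng = np.random.default_rng(seed)
    features = list(table.columns)
    x_all = table.to_numpy(dtype=np.float64)
    n, p = x_all.shape

    status = {f: "tentative" for f in features}
    hits = np.zeros(p, dtype=int)
    trials = 0
    imp_sum = np.zeros(p)
    imp_runs = 0

    for _ in range(max_iter):
        live = [i for i, f in enumerate(features) if status[f] == "tentative"]
        if not live:
            break
        x_live = x_all[:, live]
        shadows = x_live.copy()
        for k in range(shadows.shape[1]):
            rng.shuffle(shadows[:, k])
        x_aug = np.hstack([x_live, shadows])
        model = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        model.fit(x_aug, labels)
        imps = _importances(model, x_aug, labels, importance, rng)
        real, shadow = imps[: len(live)], imps[len(live) :]
        threshold = shadow.max() if len(shadow) else 0.0
        hits[live] += (real > threshold).astype(int)
        imp_sum[live] += real
        imp_runs += 1
        trials += 1

        level = alpha / p if mc_adjust else alpha  # Bonferroni over features
        for i in live:
            # two-sided binomial test on accumulated hits vs fair coin
            p_hi = stats.binom.sf(hits[i] - 1, trials, 0.5)
            p_lo = stats.binom.cdf(hits[i], trials, 0.5)
            if 2 * min(p_hi, p_lo) < level:
                status[features[i]] = "confirmed" if hits[i] > trials / 2 else "rejected"

    result = dict(status)
    result["__importance__"] = {
        f: (imp_sum[i] / max(imp_runs, 1)) for i, f in enumerate(features)
    }
    return result


def _stratified_bootstrap(
    labels: np.ndarray, rng: np.random.Generator, max_retry: int = 20
) -> np.ndarray:
    """Resample with replacement within each class (class counts preserved)."""
    idx = np.arange(len(labels))
    for _ in range(max_retry):
        parts = []
        for cls in np.unique(labels):
            members = idx[labels == cls]
            parts.append(rng.choice(members, size=len(members), replace=True))
        sample = np.concatenate(parts)
        if len(np.unique(labels[sample])) >= 2:
            return sample
    raise RuntimeError("could not draw a two-class bootstrap sample")


def bootstrap_select(
    table: pd.DataFrame,
    labels: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    *,
    cutoff: float = 0.7,
    alpha: float = 0.01,
    max_iter: int = 100,
    n_estimators: int = 100,
    importance: str = "impurity",
    mc_adjust: bool = True,
    filter_per_bootstrap: bool = True,
) -> SelectionReport:
    """Bootstrapped (Pearson filter -> Boruta) frequency ranking.

    ``filter_per_bootstrap=False`` applies the Pearson filter once on the
    full table before bootstrapping instead of inside every run.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("bootstrap_select requires both classes present")
    rng = np.random.default_rng(seed)
    work = table if filter_per_bootstrap else pearson_filter(table, cutoff)

    freq = {f: 0 for f in table.columns}
    imp_total = {f: 0.0 for f in table.columns}
    confirmed_counts = []
    for b in range(n_boot):
        sample = _stratified_bootstrap(labels, rng)
        boot = work.iloc[sample].reset_index(drop=True)
        boot_y = labels[sample]
        filtered = pearson_filter(boot, cutoff) if filter_per_bootstrap else boot
        result = boruta_run(
            filtered,
            boot_y,
            alpha=alpha,
            max_iter=max_iter,
            seed=int(rng.integers(2**31 - 1)),
            n_estimators=n_estimators,
            importance=importance,
            mc_adjust=mc_adjust,
        )
        importances = result.pop("__importance__")
        confirmed = [f for f, s in result.items() if s == "confirmed"]
        confirmed_counts.append(len(confirmed))
        for f in confirmed:
            freq[f] += 1
        for f, v in importances.items():
            imp_total[f] += v

    median = float(np.median(confirmed_counts))
    m = int(math.floor(median + 0.5))  # round half-up
    ranked = sorted(freq, key=lambda f: (-freq[f], -imp_total[f], f))
    return SelectionReport(
        frequency=freq,
        median_confirmed=m,
        final_set=ranked[:m],
        settings={
            "n_boot": n_boot,
            "seed": seed,
            "cutoff": cutoff,
            "alpha": alpha,
            "max_iter": max_iter,
            "importance": importance,
            "filter_per_bootstrap": filter_per_bootstrap,
        },
    )
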