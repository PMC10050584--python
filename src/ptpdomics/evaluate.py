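"""Nested cross-validation benchmarking of the classifier zoo.

Four classifiers are compared: random forest (rf), elastic-net logistic
regression (glmnet), RBF-kernel SVM (svmRadial) and stagewise logistic
boosting over decision stumps (logitBoost).  Evaluation runs ``n_iter``
iterations of stratified k-fold nested cross-validation: hyperparameters
are chosen by grid search on inner folds (mean inner-validation AUC),
the winner is refit on the full outer training set and scored on the
untouched outer test fold.  Class rebalancing (SMOTE) and feature
scaling are fit on training portions only; optional per-fold feature
selection runs inside the outer training set, never on test data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeRegressor

from .balance import ResampleSpec, smote_resample

__all__ = [
    "CVResult",
    "LogitBoostClassifier",
    "auc",
    "default_models",
    "default_grids",
    "nested_cv_evaluate",
    "rank_models",
    "summarize",
    "single_feature_model",
]

log = logging.getLogger(__name__)

MODEL_NAMES = ("rf", "glmnet", "svmRadial", "logitBoost")


def auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney formulation (ties count 1/2)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


class LogitBoostClassifier(BaseEstimator, ClassifierMixin):
    """Stagewise logistic boosting with depth-1 regression trees.

    Newton-style updates on the binomial log-likelihood: per stage fit a
    weighted least-squares stump to the working response
    ``z = (y - p) / (p (1 - p))`` and add half of it to the additive
    score ``F`` with ``p = sigmoid(2 F)``.
    """

    def __init__(self, n_estimators: int = 31, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, x, y):
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("LogitBoost supports binary targets only")
        yb = (y == self.classes_[1]).astype(np.float64)
        n = len(yb)
        f = np.zeros(n)
        p = np.full(n, 0.5)
        self.stumps_ = []
        for _ in range(self.n_estimators):
            w = np.clip(p * (1.0 - p), 1e-5, None)
            z = np.clip((yb - p) / w, -4.0, 4.0)
            stump = DecisionTreeRegressor(max_depth=1, random_state=self.random_state)
            stump.fit(x, z, sample_weight=w)
            f += 0.5 * stump.predict(x)
            p = 1.0 / (1.0 + np.exp(-2.0 * f))
            self.stumps_.append(stump)
        return self

    def decision_function(self, x):
        x = np.asarray(x, dtype=np.float64)
        f = np.zeros(len(x))
        for stump in self.stumps_:
            f += 0.5 * stump.predict(x)
        return 2.0 * f

    def predict_proba(self, x):
        p = 1.0 / (1.0 + np.exp(-self.decision_function(x)))
        return np.column_stack([1.0 - p, p])

    def predict(self, x):
        return self.classes_[(self.predict_proba(x)[:, 1] >= 0.5).astype(int)]


def default_models() -> dict:
    """The four-classifier zoo."""
    return {
        "rf": RandomForestClassifier(n_estimators=500, n_jobs=1),
        "glmnet": LogisticRegression(solver="saga", l1_ratio=0.5, max_iter=3000, tol=1e-3),
        "svmRadial": SVC(kernel="rbf", probability=False),
        "logitBoost": LogitBoostClassifier(),
    }


def default_grids() -> dict:
    """Hyperparameter grids searched in the inner folds."""
    return {
        "rf": {"max_features": ["sqrt", 0.25]},
        "glmnet": {"C": [0.01, 0.1, 1.0, 10.0], "l1_ratio": [0.1, 0.5, 1.0]},
        "svmRadial": {"C": [0.1, 1.0, 10.0, 100.0], "gamma": ["scale", 0.01]},
        "logitBoost": {"n_estimators": [11, 21, 31, 51]},
    }


@dataclass
class CVResult:
    """Per-(iteration, fold, model) outer-test AUCs plus bookkeeping."""

    records: pd.DataFrame  # iteration, fold, model, feature_set, auc, params
    skipped_folds: int = 0
    feature_set: str = "default"

    def mean_auc(self, model: str | None = None) -> float:
        df = self.records
        if model is not None:
            df = df[df["model"] == model]
        return float(df["auc"].mean())


def _score(model, x) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        try:
            return model.predict_proba(x)[:, 1]
        except Exception:
            pass
    return model.decision_function(x)


def _fit_and_score(model, params, x_tr, y_tr, x_te, y_te, resample, rs_seed) -> float:
    if resample is not None:
        spec = ResampleSpec(
            k_neighbors=resample.k_neighbors,
            perc_over=resample.perc_over,
            perc_under=resample.perc_under,
            seed=rs_seed,
        )
        x_tr, y_tr = smote_resample(x_tr, y_tr, spec)
    scaler = StandardScaler().fit(x_tr)
    est = clone(model).set_params(**params)
    if "random_state" in est.get_params():
        est.set_params(random_state=rs_seed % (2**31 - 1))
    est.fit(scaler.transform(x_tr), y_tr)
    return auc(_score(est, scaler.transform(x_te)), y_te)


def nested_cv_evaluate(
    table: pd.DataFrame,
    labels,
    models: dict | None = None,
    grids: dict | None = None,
    n_iter: int = 100,
    k: int = 5,
    seed: int = 0,
    *,
    resample: ResampleSpec | None = ResampleSpec(),
    selector=None,
    feature_set: str = "default",
) -> CVResult:
    """Run the nested-CV benchmark on one feature table.

    Parameters
    ----------
    table, labels
        Feature matrix (cases x features) and binary outcome.
    models, grids
        Classifier zoo and per-model hyperparameter grids; defaults to
        the four-model zoo.  Grids may be dicts (expanded by
        ``ParameterGrid``) or explicit lists of parameter dicts.
    resample
        SMOTE specification applied to every training portion (outer and
        inner); ``None`` disables rebalancing.
    selector
        Optional callable ``(table_train, y_train) -> list_of_columns``
        re-run on each outer training set (leakage-safe placement).
    """
    models = models or default_models()
    grids = grids or {m: default_grids().get(m, {}) for m in models}
    y = np.asarray(labels)
    if min(np.bincount(y)) < k:
        raise ValueError(f"need >= {k} cases per class for stratified {k}-fold CV")
    expanded = {
        m: list(ParameterGrid(g)) if isinstance(g, dict) else list(g) for m, g in grids.items()
    }
    for m, g in expanded.items():
        if len(g) == 0:
            expanded[m] = [{}]

    rng = np.random.default_rng(seed)
    rows = []
    skipped = 0
    for iteration in range(1, n_iter + 1):
        outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
        for fold, (tr_idx, te_idx) in enumerate(outer.split(table, y), start=1):
            y_tr, y_te = y[tr_idx], y[te_idx]
            if len(np.unique(y_te)) < 2 or len(np.unique(y_tr)) < 2:
                skipped += 1
                continue
            cols = list(table.columns) if selector is None else list(selector(table.iloc[tr_idx], y_tr))
            x_tr = table.iloc[tr_idx][cols].to_numpy(dtype=np.float64)
            x_te = table.iloc[te_idx][cols].to_numpy(dtype=np.float64)

            inner = StratifiedKFold(
                n_splits=k, shuffle=True, random_state=int(rng.integers(2**31 - 1))
            )
            inner_splits = [
                (a, b)
                for a, b in inner.split(x_tr, y_tr)
                if len(np.unique(y_tr[b])) == 2 and len(np.unique(y_tr[a])) == 2
            ]
            for name, model in models.items():
                best_params, best_score = None, -np.inf
                if len(expanded[name]) == 1:
                    # trivial grid: inner-fold search has nothing to choose
                    best_params = expanded[name][0]
                for params in expanded[name] if best_params is None else []:
                    scores = []
                    for a, b in inner_splits:
                        try:
                            scores.append(
                                _fit_and_score(
                                    model, params, x_tr[a], y_tr[a], x_tr[b], y_tr[b],
                                    resample, int(rng.integers(2**31 - 1)),
                                )
                            )
                        except ValueError:
                            continue
                    mean_score = float(np.mean(scores)) if scores else -np.inf
                    if mean_score > best_score:
                        best_score, best_params = mean_score, params
                fold_auc = _fit_and_score(
                    model, best_params or {}, x_tr, y_tr, x_te, y_te,
                    resample, int(rng.integers(2**31 - 1)),
                )
                rows.append(
                    {
                        "iteration": iteration,
                        "fold": fold,
                        "model": name,
                        "feature_set": feature_set,
                        "auc": fold_auc,
                        "params": repr(best_params),
                        "n_train": len(tr_idx),
                        "n_test": len(te_idx),
                    }
                )
    return CVResult(records=pd.DataFrame(rows), skipped_folds=skipped, feature_set=feature_set)


def rank_models(cv: CVResult) -> tuple[pd.DataFrame, pd.Series]:
    """Per-(iteration, fold) ranks 1..m (1 = best AUC, average ties) and
    the mean rank per model."""
    df = cv.records.copy()
    if df["model"].nunique() < 2:
        raise ValueError("ranking needs at least two models on identical folds")
    counts = df.groupby(["iteration", "fold"])["model"].nunique()
    if counts.nunique() != 1:
        raise ValueError("models were not evaluated on identical fold partitions")
    df["rank"] = df.groupby(["iteration", "fold"])["auc"].rank(ascending=False, method="average")
    return df, df.groupby("model")["rank"].mean()


def summarize(cv: CVResult, confidence: float = 0.95) -> pd.DataFrame:
    """Mean outer-fold AUC with a t-interval per (model, feature set)."""
    out = []
    for (model, fset), grp in cv.records.groupby(["model", "feature_set"]):
        vals = grp["auc"].to_numpy()
        n = len(vals)
        mean = float(vals.mean())
        if n > 1 and vals.std(ddof=1) > 0:
            half = stats.t.ppf(0.5 + confidence / 2, n - 1) * vals.std(ddof=1) / np.sqrt(n)
        else:
            half = 0.0
        out.append(
            {
                "model": model,
                "feature_set": fset,
                "n_folds": n,
                "mean_auc": mean,
                "ci_low": mean - half,
                "ci_high": mean + half,
            }
        )
    return pd.DataFrame(out)


def single_feature_model(
    feature: pd.Series,
    labels,
    n_iter: int = 100,
    k: int = 5,
    seed: int = 0,
    *,
    resample: ResampleSpec | None = None,
) -> CVResult:
    """Univariate logistic-regression AUC in the same nested-CV harness.

    Lightly regularized (ridge, C=1e4) so complete separation degrades
    gracefully instead of diverging.
    """
    table = pd.DataFrame({feature.name or "feature": np.asarray(feature, dtype=np.float64)})
    models = {"logistic": LogisticRegression(C=1e4, max_iter=2000)}
    return nested_cv_evaluate(
        table,
        labels,
        models=models,
        grids={"logistic": [{}]},
        n_iter=n_iter,
        k=k,
        seed=seed,
        resample=resample,
        feature_set=f"single:{feature.name}",
    )
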