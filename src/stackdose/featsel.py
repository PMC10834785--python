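"""Feature-selection strategies for the dose model.

Three families are provided, mirroring the common taxonomy:

* **Filter** — keep variables whose mean absolute correlation with dose
  (Pearson/Spearman/Kendall tau-b average) clears a threshold, or the top-k.
* **RFECV** — recursive feature elimination: repeatedly drop the
  least-important feature(s) of a fitted estimator, score every feature
  count by k-fold cross-validated RMSE, and keep the count that minimises
  it (ties prefer fewer features).
* **BDS** — Gini-importance-guided bidirectional search: a forward pass
  adds features in descending random-forest importance when the CV RMSE
  improves, a backward pass removes them in ascending importance, under
  lock constraints, until both passes agree.  Bidirectional wrapper search
  is used because a single greedy direction is easily trapped in a local
  optimum.

All wrappers score candidate subsets with the pooled out-of-fold RMSE of a
random-forest regressor under shared, seeded folds, so traces are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from . import metrics
from ._search import bidirectional_search
from .audit import split_cohort
from .cohort import DOSE_COLUMN, Cohort
from .corrstats import CorrReport, build_corr_report


@dataclass(frozen=True)
class ImportanceRanking:
    """Normalized Gini (impurity-decrease) importances from a forest fit."""

    importances: dict[str, float]
    seed: int

    def order(self) -> list[str]:
        """Features in descending importance (ties: name order)."""
        return sorted(self.importances, key=lambda v: (-self.importances[v], v))

    def __getitem__(self, variable: str) -> float:
        return self.importances[variable]


@dataclass(frozen=True)
class FeatureSubset:
    variables: list[str]
    method: str
    score: float | None = None  # CV RMSE of the subset, where the method computes one
    trace: list = field(default_factory=list)


def gini_importance_ranking(
    X: pd.DataFrame, y, seed: int = 0, n_estimators: int = 100
) -> ImportanceRanking:
    """Impurity-decrease importances of a random-forest regressor, normalised to sum 1."""
    if X.shape[1] < 2:
        raise ValueError("importance ranking needs at least 2 features")
    if X.shape[0] < 10:
        raise ValueError("importance ranking needs at least 10 rows")
    forest = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    forest.fit(X.to_numpy(dtype=float), np.asarray(y, dtype=float))
    imp = np.asarray(forest.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    else:  # pure-noise target: spread uniformly
        imp = np.full_like(imp, 1.0 / len(imp))
    return ImportanceRanking(importances=dict(zip(X.columns, imp)), seed=seed)


def cv_rmse_evaluator(
    X: pd.DataFrame,
    y,
    k: int = 5,
    seed: int = 0,
    estimator_factory: Callable | None = None,
) -> Callable[[frozenset], float]:
    """Pooled out-of-fold RMSE of an estimator restricted to a feature subset.

    The empty subset is scored by the fold-mean (intercept-only) predictor,
    giving wrapper searches a meaningful baseline.  Folds are shuffled once
    under ``seed`` and shared across every subset evaluated.
    """
    y = np.asarray(y, dtype=float)
    if estimator_factory is None:
        estimator_factory = lambda: RandomForestRegressor(n_estimators=100, random_state=seed)
    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(X))

    def evaluate(subset: frozenset) -> float:
        cols = sorted(subset)
        oof = np.empty_like(y)
        for tr, va in folds:
            est = DummyRegressor(strategy="mean") if not cols else estimator_factory()
            Xtr = X.iloc[tr][cols].to_numpy(dtype=float) if cols else np.zeros((len(tr), 1))
            Xva = X.iloc[va][cols].to_numpy(dtype=float) if cols else np.zeros((len(va), 1))
            try:
                est.fit(Xtr, y[tr])
                oof[va] = est.predict(Xva)
            except Exception as exc:  # pragma: no cover - estimator-specific
                raise RuntimeError(f"evaluator failed on subset {cols}: {exc}") from exc
        return metrics.rmse(y, oof)

    return evaluate


def filter_select(
    report: CorrReport, threshold: float | None = None, top_k: int | None = None
) -> FeatureSubset:
    """Correlation filter: keep variables by mean absolute correlation.

    Exactly one of ``threshold`` (keep mean_abs >= threshold) or ``top_k``
    must be given; ties at the top-k boundary break by variable-name order.
    """
    if (threshold is None) == (top_k is None):
        raise ValueError("pass exactly one of threshold or top_k")
    if not report.entries:
        raise ValueError("correlation report is empty")
    ordered = sorted(report.entries, key=lambda e: (-e.mean_abs, e.variable))
    if threshold is not None:
        kept = [e.variable for e in ordered if e.mean_abs >= threshold]
    else:
        if top_k < 1:
            raise ValueError("top_k must be at least 1")
        kept = [e.variable for e in ordered[:top_k]]
    if not kept:
        raise ValueError(f"correlation filter at threshold {threshold} keeps no variables; a model needs at least one feature")
    return FeatureSubset(variables=sorted(kept), method="filter")


def rfecv_select(
    X: pd.DataFrame,
    y,
    estimator_factory: Callable | None = None,
    k: int = 5,
    step: int = 1,
    seed: int = 0,
) -> FeatureSubset:
    """Recursive feature elimination scored by k-fold CV RMSE.

    At each round the ``step`` least-important features (from a fit on the
    full training data with the current set) are dropped; every visited
    feature count is scored by CV RMSE and the count minimising it wins,
    ties going to the smaller count.
    """
    if k < 2:
        raise ValueError("k_folds must be at least 2")
    if step < 1:
        raise ValueError("step must be at least 1")
    if X.shape[1] < 1:
        raise ValueError("no features to select from")
    if estimator_factory is None:
        estimator_factory = lambda: RandomForestRegressor(n_estimators=100, random_state=seed)
    evaluate = cv_rmse_evaluator(X, y, k=k, seed=seed, estimator_factory=estimator_factory)
    y_arr = np.asarray(y, dtype=float)
    current = list(X.columns)
    trace = []
    scored: list[tuple[float, int, tuple[str, ...]]] = []
    while True:
        score = evaluate(frozenset(current))
        scored.append((score, len(current), tuple(sorted(current))))
        trace.append({"n_features": len(current), "cv_rmse": score, "features": sorted(current)})
        if len(current) == 1:
            break
        est = estimator_factory()
        est.fit(X[current].to_numpy(dtype=float), y_arr)
        imp = getattr(est, "feature_importances_", None)
        if imp is None:
            imp = np.abs(np.ravel(est.coef_))
        order = sorted(zip(imp, current), key=lambda t: (t[0], t[1]))
        n_drop = min(step, len(current) - 1)
        dropped = [name for _, name in order[:n_drop]]
        current = [c for c in current if c not in dropped]
        trace.append({"dropped": dropped})
    best_score, _, best_feats = min(scored, key=lambda t: (t[0], t[1], t[2]))
    return FeatureSubset(variables=list(best_feats), method="rfecv", score=best_score, trace=trace)


def bds_select(
    X: pd.DataFrame,
    y,
    ranking: ImportanceRanking | None = None,
    evaluator: Callable[[frozenset], float] | None = None,
    k: int = 5,
    seed: int = 0,
) -> FeatureSubset:
    """Gini-importance-guided bidirectional wrapper search over features."""
    if ranking is None:
        ranking = gini_importance_ranking(X, y, seed=seed)
    missing = [c for c in X.columns if c not in ranking.importances]
    if missing:
        raise ValueError(f"ranking does not cover features: {missing}")
    if evaluator is None:
        evaluator = cv_rmse_evaluator(X, y, k=k, seed=seed)
    chosen, trace, state = bidirectional_search(list(X.columns), ranking.importances, evaluator)
    if not chosen:
        # nothing beat the intercept-only baseline; a model still needs one feature
        singles = {c: state.cache.get(frozenset({c}), evaluator(frozenset({c}))) for c in X.columns}
        chosen = frozenset({min(singles, key=lambda c: (singles[c], c))})
    score = state.cache.get(frozenset(chosen))
    if score is None:
        score = evaluator(frozenset(chosen))
    return FeatureSubset(variables=sorted(chosen), method="bds", score=float(score), trace=trace)


def compare_selection_methods(
    cohort: Cohort,
    seed: int = 0,
    test_fraction: float = 0.10,
    k: int = 5,
    filter_threshold: float = 0.10,
    band: float = 0.20,
    exclude: list[str] | None = None,
) -> pd.DataFrame:
    """Ideal-prediction counts of a random forest under each selection method.

    Splits the cohort, runs {original, filter, RFECV, BDS} on the training
    partition, fits a random forest per subset and counts test predictions
    within the ±``band`` relative-error window.
    """
    split = split_cohort(cohort, test_fraction=test_fraction, seed=seed)
    if len(split.test) == 0:
        raise ValueError("test partition is empty")
    exclude = list(exclude or ())
    feats = [c for c in cohort.feature_frame().columns if c not in exclude]
    Xtr = split.train.feature_frame(feats)
    ytr = split.train.dose
    Xte = split.test.feature_frame(feats)
    yte = split.test.dose

    report = build_corr_report(split.train, drop=set(exclude))
    report = CorrReport(
        entries=[e for e in report.entries if e.variable in feats], excluded=report.excluded
    )
    subsets = {
        "original": FeatureSubset(variables=sorted(feats), method="original"),
        "filter": filter_select(report, threshold=filter_threshold),
        "rfecv": rfecv_select(Xtr, ytr, k=k, seed=seed),
        "bds": bds_select(Xtr, ytr, k=k, seed=seed),
    }
    rows = []
    for method, subset in subsets.items():
        cols = [c for c in subset.variables if c in feats]
        forest = RandomForestRegressor(n_estimators=100, random_state=seed)
        forest.fit(Xtr[cols].to_numpy(dtype=float), ytr)
        pred = forest.predict(Xte[cols].to_numpy(dtype=float))
        rows.append(
            {
                "method": method,
                "n_features": len(cols),
                "ideal_count": metrics.ideal_count(yte, pred, band),
                "n_test": len(yte),
                "err_pct": metrics.err_within(yte, pred, band),
            }
        )
    return pd.DataFrame(rows)
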