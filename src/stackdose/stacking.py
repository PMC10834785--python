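"""Stacked-generalization regression with inverse-RMSE blending and learner search.

Three stacking variants are implemented over a pool of eight heterogeneous
base regressors (RF, GBRT, GPR, SGD, KRR, Bayesian ridge, MLR, SVR) with an
RBF-kernel SVR meta-learner:

* **traditional** — every base learner contributes an out-of-fold (OOF)
  prediction column to the meta-learner's training matrix Z; its test
  column is the *arithmetic* mean of its K fold-models' test predictions.
* **weighted** — identical, except each learner's K fold models are blended
  by weights proportional to the reciprocal of their validation RMSE, so
  better fold models speak louder.
* **heuristic** — inverse-RMSE blending plus a bidirectional search over
  the *learner* pool: a forward search adds learners, a backward search
  removes them, under lock constraints, scored by the k-fold CV RMSE of the
  stacked model, stopping when both searches agree.

Blending happens per learner across its own fold models — each learner
keeps one column in the stacked test matrix — so the meta-learner sees the
same width at train and test time.  A fraction of the cohort (default 10%)
is reserved up front as an untouched holdout on which the clinically
interpretable ERR±20% is computed; it never influences feature or learner
selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import BayesianRidge, LinearRegression, SGDRegressor
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from . import metrics
from ._search import bidirectional_search
from .audit import compare_split, flag_insufficient_variables, split_cohort
from .cohort import VARIABLES, Cohort
from .corrstats import build_corr_report
from .featsel import FeatureSubset, bds_select, filter_select, rfecv_select

POOL_NAMES = ("RF", "GBRT", "GPR", "SGD", "KRR", "Bayes", "MLR", "SVR")


@dataclass(frozen=True)
class LearnerSpec:
    """A named base (or meta) regressor with its hyperparameters.

    ``standardize`` wraps the estimator in a train-fitted scaler — the
    kernel and gradient methods are degenerate on raw clinical scales,
    while tree ensembles consume raw features.
    """

    name: str
    factory: Callable
    standardize: bool = False
    notes: str = ""

    def build(self):
        est = self.factory()
        if self.standardize:
            return Pipeline([("scale", StandardScaler()), ("model", est)])
        return est


def default_pool(seed: int = 0) -> dict[str, LearnerSpec]:
    """The eight-learner pool with fixed, reproducible hyperparameters."""
    return {
        "RF": LearnerSpec("RF", lambda: RandomForestRegressor(n_estimators=100, random_state=seed),
                          notes="bagging ensemble; nonlinear, low bias"),
        "GBRT": LearnerSpec("GBRT", lambda: GradientBoostingRegressor(n_estimators=100, learning_rate=0.1,
                                                                      random_state=seed),
                            notes="boosting ensemble; nonlinear"),
        "GPR": LearnerSpec("GPR", lambda: GaussianProcessRegressor(alpha=1e-10, normalize_y=True,
                                                                   random_state=seed),
                           standardize=True,
                           notes="kernel interpolator; strong in-sample, weak extrapolation"),
        "SGD": LearnerSpec("SGD", lambda: SGDRegressor(loss="squared_error", penalty="l2", alpha=1e-4,
                                                       random_state=seed),
                           standardize=True, notes="linear with L2 regularization"),
        "KRR": LearnerSpec("KRR",
                           # kernel ridge has no intercept; regress on the centred/scaled target
                           lambda: TransformedTargetRegressor(KernelRidge(kernel="linear", alpha=1.0),
                                                              transformer=StandardScaler()),
                           standardize=True, notes="linear kernel ridge (L2)"),
        "Bayes": LearnerSpec("Bayes", lambda: BayesianRidge(),
                             standardize=True, notes="Gaussian-prior linear model"),
        "MLR": LearnerSpec("MLR", lambda: LinearRegression(), notes="ordinary least squares"),
        "SVR": LearnerSpec("SVR", lambda: SVR(kernel="rbf", C=1.0, epsilon=0.1),
                           standardize=True, notes="RBF support-vector regression"),
    }


def default_meta(seed: int = 0) -> LearnerSpec:
    """RBF-kernel SVR, the meta-learner of choice."""
    return LearnerSpec("SVR", lambda: SVR(kernel="rbf", C=1.0, epsilon=0.1), standardize=True,
                       notes="meta-learner")


def make_folds(n: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Random partition of ``range(n)`` into k folds of size floor/ceil(n/k)."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} rows")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for j, chunk in enumerate(np.array_split(perm, k)):
        assignment[chunk] = j
    return assignment


@dataclass
class OofResult:
    """One base learner's cross-validation products."""

    name: str
    oof: np.ndarray  # out-of-fold predictions, aligned with training rows
    fold_test_preds: np.ndarray  # (k, n_test) test predictions of the k fold models
    val_rmses: np.ndarray  # (k,) validation RMSE of each fold model on its held-out fold
    fold_records: list[dict]  # per fold: train/validation index bookkeeping


def fit_base_out_of_fold(
    spec: LearnerSpec, X_train: np.ndarray, y_train: np.ndarray, folds: np.ndarray,
    X_test: np.ndarray | None = None,
) -> OofResult:
    """Fit one learner per fold; collect OOF predictions and validation RMSEs.

    Row ``i`` of the OOF column is predicted by the model whose training
    excluded fold(i), which is what lets the meta-learner train without
    seeing leaked in-sample fits.
    """
    k = int(folds.max()) + 1
    n = len(y_train)
    oof = np.empty(n, dtype=float)
    val_rmses = np.empty(k, dtype=float)
    test_preds = []
    records = []
    for j in range(k):
        va = np.flatnonzero(folds == j)
        tr = np.flatnonzero(folds != j)
        model = spec.build()
        try:
            model.fit(X_train[tr], y_train[tr])
        except Exception as exc:
            raise RuntimeError(f"base learner {spec.name!r} failed on fold {j}: {exc}") from exc
        oof[va] = model.predict(X_train[va])
        val_rmses[j] = metrics.rmse(y_train[va], oof[va])
        if X_test is not None:
            test_preds.append(model.predict(X_test))
        records.append({"fold": j, "train_indices": tr, "val_indices": va})
    return OofResult(
        name=spec.name,
        oof=oof,
        fold_test_preds=np.vstack(test_preds) if test_preds else np.empty((k, 0)),
        val_rmses=val_rmses,
        fold_records=records,
    )


def blend_test_predictions(fold_preds: np.ndarray, mode: str, val_rmses=None) -> np.ndarray:
    """Collapse K fold-model test predictions into one column.

    ``arithmetic`` averages the K rows; ``inverse_rmse`` weights row j by
    ``(1/RMSE_j) / sum(1/RMSE)`` so fold models that validated better count
    more.  A zero validation RMSE makes the reciprocal weights degenerate —
    use arithmetic mode for that (perfect-fold) case.
    """
    P = np.asarray(fold_preds, dtype=float)
    if P.ndim != 2 or P.shape[0] < 1:
        raise ValueError("fold_preds must be a (k, n_test) matrix with k >= 1")
    if mode == "arithmetic":
        return P.mean(axis=0)
    if mode == "inverse_rmse":
        r = np.asarray(val_rmses, dtype=float)
        if r.shape != (P.shape[0],):
            raise ValueError("need one validation RMSE per fold model")
        if np.any(r <= 0):
            raise ValueError(
                "zero validation RMSE: reciprocal weights are undefined; "
                "use arithmetic blending for perfect fold models"
            )
        w = (1.0 / r) / np.sum(1.0 / r)
        return w @ P
    raise ValueError(f"unknown blend mode {mode!r}")


@dataclass
class StackedDataset:
    """The level-one dataset: OOF train matrix Z and blended test matrix Z*."""

    Z: pd.DataFrame  # (n_train, |B|) out-of-fold predictions
    Z_test: pd.DataFrame  # (n_test, |B|) blended test predictions
    val_rmses: dict[str, np.ndarray]  # per learner, (k,) validation RMSEs
    fold_assignment: np.ndarray
    mode: str
    fold_records: dict[str, list[dict]]
    fold_test_preds: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def learner_names(self) -> list[str]:
        return list(self.Z.columns)

    def with_mode(self, mode: str) -> "StackedDataset":
        """Re-blend the stored fold test predictions under another mode."""
        Z_test = pd.DataFrame(
            {name: blend_test_predictions(self.fold_test_preds[name], mode, self.val_rmses[name])
             for name in self.learner_names}
        )
        return StackedDataset(
            Z=self.Z, Z_test=Z_test, val_rmses=self.val_rmses,
            fold_assignment=self.fold_assignment, mode=mode,
            fold_records=self.fold_records, fold_test_preds=self.fold_test_preds,
        )

    def check_no_leakage(self) -> None:
        """Verify the fold bookkeeping: no fold model saw its own validation rows."""
        n = len(self.fold_assignment)
        for name, records in self.fold_records.items():
            seen = np.zeros(n, dtype=bool)
            for rec in records:
                tr, va = np.asarray(rec["train_indices"]), np.asarray(rec["val_indices"])
                overlap = np.intersect1d(tr, va)
                if overlap.size:
                    raise AssertionError(
                        f"leakage: learner {name!r} fold {rec['fold']} trained on its own "
                        f"validation rows {overlap[:5].tolist()}"
                    )
                if seen[va].any():
                    raise AssertionError(f"learner {name!r}: validation folds overlap")
                seen[va] = True
            if not seen.all():
                raise AssertionError(f"learner {name!r}: validation folds do not cover all rows")


def build_stacked_dataset(
    pool: dict[str, LearnerSpec],
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    k: int = 5,
    seed: int = 0,
    mode: str = "inverse_rmse",
) -> StackedDataset:
    """Run every pool learner through k-fold CV and assemble Z and Z*."""
    if not pool:
        raise ValueError("learner pool is empty")
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    folds = make_folds(len(y_train), k=k, seed=seed)
    Z, Z_test, rmses, records, raw = {}, {}, {}, {}, {}
    for name, spec in pool.items():
        res = fit_base_out_of_fold(spec, X_train, y_train, folds, X_test)
        Z[name] = res.oof
        Z_test[name] = blend_test_predictions(res.fold_test_preds, mode, res.val_rmses)
        rmses[name] = res.val_rmses
        records[name] = res.fold_records
        raw[name] = res.fold_test_preds
    stacked = StackedDataset(
        Z=pd.DataFrame(Z), Z_test=pd.DataFrame(Z_test), val_rmses=rmses,
        fold_assignment=folds, mode=mode, fold_records=records, fold_test_preds=raw,
    )
    stacked.check_no_leakage()
    return stacked


def fit_meta_and_predict(
    stacked: StackedDataset, y_train: np.ndarray, meta: LearnerSpec | None = None,
    learners: list[str] | None = None,
) -> np.ndarray:
    """Fit the meta-learner on (Z, y) and predict the blended test matrix Z*."""
    meta = meta or default_meta()
    names = learners if learners is not None else stacked.learner_names
    missing = [n for n in names if n not in stacked.Z.columns]
    if missing:
        raise ValueError(f"unknown learners: {missing}")
    Z = stacked.Z[names].to_numpy(dtype=float)
    Zt = stacked.Z_test[names].to_numpy(dtype=float)
    if Z.shape[0] != len(y_train):
        raise ValueError("stacked train matrix and targets disagree in length")
    model = meta.build()
    model.fit(Z, np.asarray(y_train, dtype=float))
    return model.predict(Zt)


def stack_cv_scorer(
    stacked: StackedDataset, y_train: np.ndarray, meta: LearnerSpec | None = None,
    k: int = 5, seed: int = 0,
) -> Callable[[frozenset], float]:
    """k-fold CV RMSE of the stacked model restricted to a learner subset.

    The base level is already cross-validated (Z holds out-of-fold
    predictions), so scoring a learner subset only requires refitting the
    meta-learner on the corresponding Z columns under shared folds.  The
    empty subset is infeasible and scores +inf.
    """
    meta = meta or default_meta()
    y = np.asarray(y_train, dtype=float)
    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(y))

    def evaluate(subset: frozenset) -> float:
        if not subset:
            return float("inf")
        names = sorted(subset)
        Z = stacked.Z[names].to_numpy(dtype=float)
        oof = np.empty_like(y)
        for tr, va in folds:
            model = meta.build()
            try:
                model.fit(Z[tr], y[tr])
            except Exception as exc:
                raise RuntimeError(f"meta-learner failed on learner subset {names}: {exc}") from exc
            oof[va] = model.predict(Z[va])
        return metrics.rmse(y, oof)

    return evaluate


@dataclass
class EnsembleResult:
    """Outcome of one stacking run: the chosen ensemble and its holdout report."""

    variant: str
    learners: list[str]
    features: list[str]
    feature_method: str
    report: metrics.EvalReport
    seed: int
    search_trace: list = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        payload = {
            "variant": self.variant,
            "learners": self.learners,
            "features": self.features,
            "feature_method": self.feature_method,
            "report": self.report.as_dict(),
            "seed": self.seed,
            "excluded": self.excluded,
            "search_trace": self.search_trace,
            "extra": self.extra,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=_json_default, **kwargs)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def heuristic_learner_search(
    pool: dict[str, LearnerSpec],
    stacked: StackedDataset,
    y_train: np.ndarray,
    meta: LearnerSpec | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[list[str], list[dict], float]:
    """Bidirectional search over the learner pool on a prebuilt stacked dataset.

    Candidate order within a pass is descending single-learner CV
    performance (best learners are offered to the forward search first and
    to the backward search last).  Returns the agreed learner set, the
    search trace, and the winning CV RMSE.
    """
    if not pool:
        raise ValueError("learner pool is empty")
    names = [n for n in stacked.learner_names if n in pool]
    scorer = stack_cv_scorer(stacked, y_train, meta=meta, k=k, seed=seed)
    priority = {n: -scorer(frozenset({n})) for n in names}  # low single RMSE = high priority
    chosen, trace, state = bidirectional_search(names, priority, scorer)
    if not chosen:  # infeasible-empty guard; the best single learner always exists
        chosen = frozenset({max(priority, key=lambda n: (priority[n], n))})
    score = state.cache.get(frozenset(chosen), scorer(frozenset(chosen)))
    return sorted(chosen), trace, float(score)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run settings; one seed drives every stochastic stage."""

    seed: int = 0
    variant: str = "heuristic"  # traditional | weighted | heuristic
    holdout_fraction: float = 0.10
    k: int = 5
    selection: str = "bds"  # none | filter | rfecv | bds
    filter_threshold: float = 0.10
    min_events: int = 5
    alpha: float = 0.05
    band: float = 0.20
    pool: tuple[str, ...] = POOL_NAMES

    def blend_mode(self) -> str:
        return "arithmetic" if self.variant == "traditional" else "inverse_rmse"


def _stage_seeds(seed: int, n: int = 6) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_pipeline(cohort: Cohort, config: PipelineConfig | None = None) -> EnsembleResult:
    """The full study pipeline on one cohort.

    Stage order matters for leakage control: (1) reserve the holdout;
    (2) audit the split and exclude under-evented flags; (3) select features
    on the 90% partition only; (4) build the stacked dataset and (for the
    heuristic variant) search the learner pool, all inside the 90%;
    (5) score the untouched holdout.
    """
    config = config or PipelineConfig()
    if config.variant not in ("traditional", "weighted", "heuristic"):
        raise ValueError(f"unknown variant {config.variant!r}")
    if config.selection not in ("none", "filter", "rfecv", "bds"):
        raise ValueError(f"unknown selection method {config.selection!r}")
    s_split, s_feat, s_fold, s_search, s_learn, _ = _stage_seeds(config.seed)
    min_rows = max(config.k * 2, int(np.ceil(1 / config.holdout_fraction)))
    if len(cohort) < min_rows:
        raise ValueError(f"cohort too small for the pipeline (need >= {min_rows} rows)")

    split = split_cohort(cohort, test_fraction=config.holdout_fraction, seed=s_split)
    comparison = compare_split(split, alpha=config.alpha, seed=s_split)
    exclusions = flag_insufficient_variables(split, min_events=config.min_events)
    candidates = exclusions.retained(list(VARIABLES))

    Xtr_full = split.train.feature_frame(candidates)
    ytr = split.train.dose
    if config.selection == "none":
        subset = FeatureSubset(variables=sorted(candidates), method="none")
    elif config.selection == "filter":
        rep = build_corr_report(split.train)
        rep_entries = [e for e in rep.entries if e.variable in candidates]
        subset = filter_select(type(rep)(entries=rep_entries, excluded=rep.excluded),
                               threshold=config.filter_threshold)
    elif config.selection == "rfecv":
        subset = rfecv_select(Xtr_full, ytr, k=config.k, seed=s_feat)
    else:
        subset = bds_select(Xtr_full, ytr, k=config.k, seed=s_feat)

    feats = [c for c in subset.variables if c in candidates]
    Xtr = split.train.feature_frame(feats).to_numpy(dtype=float)
    Xte = split.test.feature_frame(feats).to_numpy(dtype=float)
    yte = split.test.dose

    pool = {n: s for n, s in default_pool(seed=s_learn).items() if n in config.pool}
    if not pool:
        raise ValueError("configured pool selects no learners")
    meta = default_meta(seed=s_learn)
    stacked = build_stacked_dataset(pool, Xtr, ytr, Xte, k=config.k, seed=s_fold,
                                    mode=config.blend_mode())
    if config.variant == "heuristic":
        learners, trace, cv_score = heuristic_learner_search(
            pool, stacked, ytr, meta=meta, k=config.k, seed=s_search
        )
    else:
        learners, trace, cv_score = sorted(pool), [], None
    pred = fit_meta_and_predict(stacked, ytr, meta=meta, learners=learners)
    report = metrics.eval_report(yte, pred, band=config.band)
    return EnsembleResult(
        variant=config.variant,
        learners=learners,
        features=feats,
        feature_method=subset.method,
        report=report,
        seed=config.seed,
        search_trace=trace,
        excluded=exclusions.excluded,
        extra={
            "cv_rmse": cv_score,
            "holdout_indices": split.test_indices.tolist(),
            "holdout_predictions": pred.tolist(),
            "stage_seeds": {"split": s_split, "features": s_feat, "folds": s_fold,
                            "search": s_search, "learners": s_learn},
            "n_flagged_imbalanced": int(comparison["flagged"].sum()),
            "blend_mode": config.blend_mode(),
        },
    )
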