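"""Regression performance measures for dose-prediction models.

Four indicators are used throughout the package to score a model on a
test set of actual stable doses ``y`` (mg/day) and predictions ``yhat``:

* **MAE** — mean absolute error, in mg/day.
* **RMSE** — root mean square error, in mg/day.
* **R²** — coefficient of determination, ``1 - SS_res / SS_tot``;
  may be negative for models worse than the mean predictor.
* **ERR±20%** — the percentage of patients whose predicted dose falls
  within ±20% *relative* error of the actual dose (the IWPC notion of a
  clinically ideal dose): ``100 · D_ideal / D_test``.

The ±20% band is relative to the actual dose and inclusive: a patient
counts as ideal when ``|yhat - y| / y <= band``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _as_arrays(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if y.ndim != 1 or p.ndim != 1:
        raise ValueError("expected 1-d vectors of actual and predicted doses")
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.size} actual vs {p.size} predicted")
    if y.size == 0:
        raise ValueError("empty prediction set")
    return y, p


@dataclass(frozen=True)
class PredictionSet:
    """Actual and predicted doses for one model on one test set."""

    actual: np.ndarray
    predicted: np.ndarray

    def __post_init__(self):
        y, p = _as_arrays(self.actual, self.predicted)
        object.__setattr__(self, "actual", y)
        object.__setattr__(self, "predicted", p)

    @property
    def n(self) -> int:
        return int(self.actual.size)

    @property
    def mean_actual(self) -> float:
        return float(self.actual.mean())


def mae(y_true, y_pred) -> float:
    """Mean absolute error (mg/day)."""
    y, p = _as_arrays(y_true, y_pred)
    return float(np.mean(np.abs(p - y)))


def rmse(y_true, y_pred) -> float:
    """Root mean square error (mg/day)."""
    y, p = _as_arrays(y_true, y_pred)
    return float(np.sqrt(np.mean((p - y) ** 2)))


def r2(y_true, y_pred) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``.

    Requires at least two observations and a non-constant actual vector;
    with zero total sum of squares the statistic is undefined.
    """
    y, p = _as_arrays(y_true, y_pred)
    if y.size < 2:
        raise ValueError("R^2 needs at least two observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: actual doses are all equal (zero total sum of squares)")
    ss_res = float(np.sum((y - p) ** 2))
    return 1.0 - ss_res / ss_tot


def err_within(y_true, y_pred, band: float = 0.20) -> float:
    """Percentage of predictions within ``band`` relative error of the actual dose.

    ``100 * D_ideal / D_test`` where ``D_ideal = #{i : |yhat_i - y_i| / y_i <= band}``.
    All actual doses must be positive for the relative error to be defined.
    """
    y, p = _as_arrays(y_true, y_pred)
    if band < 0:
        raise ValueError("band must be nonnegative")
    if np.any(y <= 0):
        raise ValueError("relative error undefined: nonpositive actual dose present")
    d_ideal = int(np.sum(np.abs(p - y) / y <= band))
    return 100.0 * d_ideal / y.size


def ideal_count(y_true, y_pred, band: float = 0.20) -> int:
    """Number of predictions within the relative-error band (D_ideal)."""
    y, p = _as_arrays(y_true, y_pred)
    if np.any(y <= 0):
        raise ValueError("relative error undefined: nonpositive actual dose present")
    return int(np.sum(np.abs(p - y) / y <= band))


@dataclass(frozen=True)
class EvalReport:
    """The four indicators for one model on one test set."""

    r2: float
    rmse: float
    mae: float
    err_pct: float
    d_ideal: int
    d_test: int
    band: float = 0.20

    def as_dict(self) -> dict:
        return {
            "r2": self.r2,
            "rmse": self.rmse,
            "mae": self.mae,
            "err_pct": self.err_pct,
            "d_ideal": self.d_ideal,
            "d_test": self.d_test,
            "band": self.band,
        }

    def format_row(self, label: str = "") -> str:
        return (
            f"{label:<24s} R2={self.r2:6.3f}  RMSE={self.rmse:6.3f}  "
            f"MAE={self.mae:6.3f}  ERR±{int(self.band * 100)}%={self.err_pct:6.2f}%"
        )


def eval_report(y_true, y_pred, band: float = 0.20) -> EvalReport:
    """Bundle R², RMSE, MAE and ERR±band into one report."""
    y, p = _as_arrays(y_true, y_pred)
    return EvalReport(
        r2=r2(y, p),
        rmse=rmse(y, p),
        mae=mae(y, p),
        err_pct=err_within(y, p, band),
        d_ideal=ideal_count(y, p, band),
        d_test=int(y.size),
        band=band,
    )
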