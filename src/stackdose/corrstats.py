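"""Correlation ranking of cohort variables against stable dose.

Three coefficients are computed per variable — Pearson's r, Spearman's rho
(Pearson on midranks) and Kendall's tau-b (tie-corrected in both margins) —
and aggregated as the arithmetic mean of their absolute values.  Ranking by
the mean absolute value lets linear (Pearson) and monotone-nonlinear
(rank-based) association speak with one voice; binary clinical flags are
correlated as 0/1 numerics, which under Pearson is the point-biserial
coefficient.  p-values accompany each coefficient but play no role in the
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DOSE_COLUMN, VARIABLES, Cohort

METHODS = ("pearson", "spearman", "kendall_tau_b")


class ConstantVariableError(ValueError):
    """A correlation was requested against a zero-variance vector."""


def _check_pair(x, y, name: str = "x") -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ConstantVariableError(f"variable {name!r} is constant; correlation undefined")
    if np.ptp(y) == 0:
        raise ConstantVariableError("target vector is constant; correlation undefined")
    return x, y


def corr_coefficient(x, y, method: str = "pearson", name: str = "x") -> tuple[float, float]:
    """One correlation coefficient and its p-value.

    ``spearman`` is Pearson on midranks; ``kendall_tau_b`` uses the
    tie-corrected denominator sqrt((n0 - T_x)(n0 - T_y)).  p-values use the
    t approximation for Pearson/Spearman and the normal approximation for
    tau-b.
    """
    x, y = _check_pair(x, y, name)
    if method == "pearson":
        res = stats.pearsonr(x, y)
        return float(res.statistic), float(res.pvalue)
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)
    if method == "kendall_tau_b":
        res = stats.kendalltau(x, y, variant="b", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def mean_abs_correlation(pearson: float, spearman: float, tau_b: float) -> float:
    """Arithmetic mean of the absolute values of the three coefficients."""
    for c in (pearson, spearman, tau_b):
        if not -1.0 - 1e-12 <= c <= 1.0 + 1e-12:
            raise ValueError(f"coefficient out of [-1, 1]: {c}")
    return (abs(pearson) + abs(spearman) + abs(tau_b)) / 3.0


@dataclass(frozen=True)
class CorrEntry:
    variable: str
    pearson: float
    spearman: float
    tau_b: float
    mean_abs: float
    negative: bool  # consensus sign (majority of the three) is negative
    p_pearson: float
    p_spearman: float
    p_tau_b: float


@dataclass(frozen=True)
class CorrReport:
    """Entries sorted by mean_abs descending; exclusions carry a reason."""

    entries: list[CorrEntry]
    excluded: dict[str, str] = field(default_factory=dict)

    def variables(self) -> list[str]:
        return [e.variable for e in self.entries]

    def entry(self, variable: str) -> CorrEntry:
        for e in self.entries:
            if e.variable == variable:
                return e
        raise KeyError(variable)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": e.variable,
                    "pearson": e.pearson,
                    "spearman": e.spearman,
                    "tau_b": e.tau_b,
                    "mean_abs": e.mean_abs,
                    "sign": "-" if e.negative else "+",
                    "p_pearson": e.p_pearson,
                    "p_spearman": e.p_spearman,
                    "p_tau_b": e.p_tau_b,
                }
                for e in self.entries
            ]
        )


def build_corr_report(cohort: Cohort, drop: set[str] | None = None) -> CorrReport:
    """Correlate every schema variable against dose and rank by mean_abs.

    ``drop`` removes variables from the report up front — the published
    analysis runs twice, once in full and once with the dominant CYP2C9 and
    VKORC1 genotypes removed to expose weaker associations.  Constant
    variables are routed to the exclusion list rather than erroring out.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    drop = set(drop or ())
    unknown = drop - set(VARIABLES)
    if unknown:
        raise KeyError(f"unknown variables in drop set: {sorted(unknown)}")
    y = cohort.frame[DOSE_COLUMN].to_numpy(dtype=float)
    entries: list[CorrEntry] = []
    excluded: dict[str, str] = {v: "dropped by request" for v in sorted(drop)}
    for var in VARIABLES:
        if var in drop:
            continue
        x = cohort.frame[var].to_numpy(dtype=float)
        try:
            r, p_r = corr_coefficient(x, y, "pearson", name=var)
            rho, p_rho = corr_coefficient(x, y, "spearman", name=var)
            tau, p_tau = corr_coefficient(x, y, "kendall_tau_b", name=var)
        except ConstantVariableError:
            excluded[var] = "constant in cohort; correlation undefined"
            continue
        signs = np.sign([r, rho, tau])
        entries.append(
            CorrEntry(
                variable=var,
                pearson=r,
                spearman=rho,
                tau_b=tau,
                mean_abs=mean_abs_correlation(r, rho, tau),
                negative=bool(signs.sum() < 0),
                p_pearson=p_r,
                p_spearman=p_rho,
                p_tau_b=p_tau,
            )
        )
    entries.sort(key=lambda e: (-e.mean_abs, e.variable))
    return CorrReport(entries=entries, excluded=excluded)
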