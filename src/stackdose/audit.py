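"""Train/test splitting and leakage auditing.

The cohort is split at random into a training set (default 90%) and a test
set (10%).  Because rare clinical flags (co-medications, rare genotypes)
can end up concentrated in one partition, the split is then *audited*:
every variable's train-vs-test distribution is compared — a Welch
two-sample t-test for continuous variables, Fisher's exact test for binary
flags, and a Fisher–Freeman–Halton-style exact test for the 3-level
genotypes.  Variables whose event counts are too small to support the
exact test are flagged for exclusion from model training (they would let a
model memorise which partition a rare carrier fell into), while remaining
available to the correlation analysis.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BINARY, CONTINUOUS, DOSE_COLUMN, ORDINAL, VARIABLES, Cohort


@dataclass
class SplitResult:
    train: Cohort
    test: Cohort
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    test_fraction: float
    comparison: pd.DataFrame | None = None


def split_cohort(cohort: Cohort, test_fraction: float = 0.10, seed: int = 0) -> SplitResult:
    """Simple random split; the test set gets ``floor(fraction * n)`` records.

    Balance is verified post hoc by :func:`compare_split` rather than
    enforced by stratification.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    n = len(cohort)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_test = int(math.floor(test_fraction * n))
    if n_test < 1:
        raise ValueError(f"test_fraction {test_fraction} yields an empty test set for n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return SplitResult(
        train=cohort.subset(train_idx),
        test=cohort.subset(test_idx),
        train_indices=train_idx,
        test_indices=test_idx,
        seed=seed,
        test_fraction=test_fraction,
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Two-sided by summing the probabilities of all hypergeometric tables (same
    margins) no more probable than the observed one.  A table with a zero row
    margin and a zero column margin simultaneously is degenerate: p = 1 with
    a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of nonnegative integer counts")
    if t.sum() < 1:
        raise ValueError("grand total must be at least 1")
    if (t.sum(axis=1) == 0).any() and (t.sum(axis=0) == 0).any():
        warnings.warn("degenerate 2x2 table (zero row and zero column margin); p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


def _log_table_prob(table: np.ndarray) -> float:
    # multivariate hypergeometric probability of an r x c table given its margins
    lg = math.lgamma
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    num = sum(lg(m + 1) for m in row) + sum(lg(m + 1) for m in col)
    den = lg(n + 1) + sum(lg(int(c) + 1) for c in table.flat)
    return num - den


def fisher_freeman_halton(table, max_exact_total: int = 200, mc_samples: int = 20000, seed: int = 0) -> float:
    """Exact (or Monte-Carlo) test of independence for a 2 x k count table.

    Full enumeration of all tables with the observed margins when the grand
    total is at most ``max_exact_total``; otherwise Monte Carlo under the
    fixed-margin null with a fixed seed.  The p-value sums/estimates the
    probability mass of tables no more probable than the observed one.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2 or (t < 0).any():
        raise ValueError("expected a 2 x k table of nonnegative integer counts")
    n = int(t.sum())
    if n < 1:
        raise ValueError("grand total must be at least 1")
    col = t.sum(axis=0)
    row = t.sum(axis=1)
    if (col > 0).sum() < 2 or (row > 0).sum() < 2:
        return 1.0  # no variation in one margin: independence is vacuous
    obs_lp = _log_table_prob(t)
    tol = 1e-9
    if n <= max_exact_total:
        # enumerate the first row; the second row is determined by the margins
        p = 0.0
        ranges = [range(min(row[0], col[j]) + 1) for j in range(t.shape[1] - 1)]
        for first in itertools.product(*ranges):
            s = sum(first)
            last = row[0] - s
            if last < 0 or last > col[-1]:
                continue
            cand = np.vstack([np.array(list(first) + [last]), col - np.array(list(first) + [last])])
            if (cand < 0).any():
                continue
            lp = _log_table_prob(cand)
            if lp <= obs_lp + tol:
                p += math.exp(lp)
        return float(min(p, 1.0))
    rng = np.random.default_rng(seed)
    # draw first-row cell counts from the multivariate hypergeometric null
    draws = rng.multivariate_hypergeometric(col, int(row[0]), size=mc_samples)
    hits = 0
    for d in draws:
        cand = np.vstack([d, col - d])
        if _log_table_prob(cand) <= obs_lp + tol:
            hits += 1
    return float((hits + 1) / (mc_samples + 1))


def compare_split(
    split: SplitResult,
    alpha: float = 0.05,
    continuous_test: str = "welch_t",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-variable train-vs-test comparison table.

    Continuous variables get a Welch two-sample t-test (a binned chi-squared
    test is available via ``continuous_test='binned_chi2'``); binary flags
    get Fisher's exact test on the 2x2 train/test x present/absent table;
    3-level genotypes get the Fisher–Freeman–Halton exact test.  Cells with
    no variation are marked non-computable rather than dropped.  The result
    is also stored on ``split.comparison``.
    """
    if continuous_test not in ("welch_t", "binned_chi2"):
        raise ValueError(f"unknown continuous_test {continuous_test!r}")
    tr, te = split.train.frame, split.test.frame
    if len(tr) == 0 or len(te) == 0:
        raise ValueError("both partitions must be nonempty")
    rows = []
    for var, kind in list(VARIABLES.items()) + [(DOSE_COLUMN, "continuous")]:
        a = tr[var].to_numpy(dtype=float)
        b = te[var].to_numpy(dtype=float)
        p: float | None
        if kind == "continuous":
            if np.ptp(np.concatenate([a, b])) == 0:
                test_name, p = continuous_test, None
            elif continuous_test == "welch_t":
                test_name = "welch_t"
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            else:
                test_name = "binned_chi2"
                edges = np.unique(np.quantile(a, [0.25, 0.5, 0.75]))
                ca = np.bincount(np.digitize(a, edges), minlength=len(edges) + 1)
                cb = np.bincount(np.digitize(b, edges), minlength=len(edges) + 1)
                tab = np.vstack([ca, cb])
                tab = tab[:, tab.sum(axis=0) > 0]
                p = float(stats.chi2_contingency(tab).pvalue) if tab.shape[1] > 1 else None
        elif kind == "binary":
            pos = np.array([a.sum(), b.sum()], dtype=int)
            neg = np.array([len(a) - pos[0], len(b) - pos[1]], dtype=int)
            test_name = "fisher_exact"
            if pos.sum() == 0 or neg.sum() == 0:
                p = None  # no variation: the test is not computable
            else:
                p = fisher_exact_2x2(np.column_stack([pos, neg]))
        else:  # 3-level genotype
            tab = np.vstack(
                [np.bincount(a.astype(int), minlength=3), np.bincount(b.astype(int), minlength=3)]
            )
            test_name = "fisher_freeman_halton"
            p = fisher_freeman_halton(tab, seed=seed) if (tab.sum(axis=0) > 0).sum() >= 2 else None
        rows.append(
            {
                "variable": var,
                "kind": kind,
                "test": test_name,
                "p_value": p,
                "computable": p is not None,
                "flagged": (p is not None and p < alpha),
            }
        )
    table = pd.DataFrame(rows)
    split.comparison = table
    return table


@dataclass(frozen=True)
class ExclusionList:
    """Variables excluded from model training, with per-variable reasons.

    Excluded variables stay available to correlation analysis; the rule only
    guards the supervised-learning stage against leakage through rare events.
    """

    excluded: dict[str, str] = field(default_factory=dict)
    min_events: int = 5

    @property
    def names(self) -> list[str]:
        return sorted(self.excluded)

    def retained(self, variables=None) -> list[str]:
        pool = list(variables) if variables is not None else list(VARIABLES)
        return [v for v in pool if v not in self.excluded]


def flag_insufficient_variables(split: SplitResult, min_events: int = 5) -> ExclusionList:
    """Exclude binary variables whose event counts cannot support the audit.

    A binary flag is excluded from modelling when its total number of
    positive events is below ``min_events`` or when the test partition holds
    zero positives (the exact test then says nothing about balance, and the
    variable risks leaking partition identity).  Continuous and ordinal
    variables are never excluded by this rule.
    """
    if min_events < 0:
        raise ValueError("min_events must be nonnegative")
    excluded: dict[str, str] = {}
    tr, te = split.train.frame, split.test.frame
    for var in BINARY:
        total = int(tr[var].sum() + te[var].sum())
        test_pos = int(te[var].sum())
        if total < min_events:
            excluded[var] = f"only {total} positive events in the cohort (min_events={min_events})"
        elif test_pos == 0:
            excluded[var] = "zero positive events in the test partition"
    return ExclusionList(excluded=excluded, min_events=min_events)
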