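"""Patient cohort model, CSV I/O, dose bands, and the synthetic-cohort generator.

The package targets warfarin stable-dose prediction in heart-valve-surgery
patients.  Real cohorts of this kind are private, so the generator here
emulates one: each variable's marginal distribution defaults to the
published summary statistics of a 641-patient southern-Chinese cohort
(continuous variables as mean/SD, categorical as prevalence, genotypes as
frequency vectors), and the stable dose is produced by a configurable
ground-truth model mixing linear covariate effects, nonlinear terms (an
age x VKORC1 interaction and a saturating square-root weight effect) and
multiplicative lognormal noise.  The mix of linear and nonlinear effects
is deliberate: it is the regime that motivates stacking heterogeneous
linear and nonlinear learners in the first place.

Genotypes are encoded ordinally by variant-allele count:

* ``cyp2c9`` — number of *3 alleles (0 = *1/*1, 1 = *1/*3, 2 = *3/*3)
* ``vkorc1`` — number of -1173 T alleles (0 = CC, 1 = TC, 2 = TT)

Each additional variant allele lowers the required dose, matching the
well-replicated pharmacogenomic direction of effect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

DOSE_COLUMN = "dose_mg_day"

#: Variable schema: name -> kind.  Order is the canonical column order.
VARIABLES: dict[str, str] = {
    "sex": "binary",  # male = 1
    "age": "continuous",
    "height": "continuous",
    "weight": "continuous",
    "han_chinese": "binary",
    "smoking": "binary",
    "drinking": "binary",
    "cyp2c9": "ordinal",
    "vkorc1": "ordinal",
    "mhvr": "binary",
    "bhvr": "binary",
    "mvr": "binary",
    "avr": "binary",
    "tvr": "binary",
    "thrombus_removal": "binary",
    "hypertension": "binary",
    "chd": "binary",
    "diabetes": "binary",
    "afib": "binary",
    "hsebo": "binary",
    "pses": "binary",
    "increase_inr": "binary",
    "decrease_inr": "binary",
    "amiodarone": "binary",
    "tartine": "binary",
    "inducer": "binary",
    "thyroxine": "binary",
    "fluconazole": "binary",
    "aspirin": "binary",
}

CONTINUOUS = [v for v, k in VARIABLES.items() if k == "continuous"]
BINARY = [v for v, k in VARIABLES.items() if k == "binary"]
ORDINAL = [v for v, k in VARIABLES.items() if k == "ordinal"]

#: Physiologic truncation bounds for the continuous variables.
TRUNCATION_BOUNDS = {"age": (18.0, 90.0), "height": (130.0, 200.0), "weight": (30.0, 120.0)}

CYP2C9_LABELS = ("*1/*1", "*1/*3", "*3/*3")
VKORC1_LABELS = ("CC", "TC", "TT")


@dataclass(frozen=True)
class DoseModel:
    """Ground-truth stable-dose model used by the generator.

    ``dose = clip(intercept + linear terms + nonlinear terms, bounds) * exp(eps)``
    with ``eps ~ N(0, noise_sd)`` (multiplicative lognormal noise keeps doses
    positive; ``noise_sd = 0`` makes the map deterministic).  Continuous
    covariates enter centred at ``centers`` so the intercept is the dose of
    the reference patient (all binaries 0, zero variant alleles, continuous
    covariates at their centres).
    """

    intercept: float = 5.0
    linear: dict[str, float] = field(
        default_factory=lambda: {
            "age": -0.020,  # mg/day per year above 45
            "height": 0.008,
            "sex": 0.15,
            "smoking": 0.40,
            "cyp2c9": -0.90,  # per *3 allele
            "vkorc1": -0.90,  # per T allele
            "mhvr": 0.20,
            "avr": 0.20,
            "afib": 0.10,
            "hypertension": 0.15,
            "chd": 0.10,
            "hsebo": -0.40,
            "amiodarone": -0.60,
            "fluconazole": -0.50,
            "increase_inr": -0.30,
            "decrease_inr": 0.30,
            "aspirin": 0.10,
        }
    )
    centers: dict[str, float] = field(
        default_factory=lambda: {"age": 45.0, "height": 160.0, "weight": 56.0}
    )
    #: nonlinear age x VKORC1 interaction, mg/day per (decade above 45) per T allele
    age_vkorc1_coef: float = -0.15
    #: saturating weight effect, mg/day per unit of sqrt(kg) above sqrt(center)
    sqrt_weight_coef: float = 0.60
    noise_sd: float = 0.12
    dose_bounds: tuple[float, float] = (0.5, 10.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic cohort configuration; defaults mirror the published cohort.

    Continuous marginals are truncated normals; binary variables are
    Bernoulli; genotypes are categorical draws from 3-level frequency
    vectors.  MHVR and BHVR are complementary (every patient underwent
    exactly one of the two valve-replacement types).
    """

    n: int = 641
    seed: int = 0
    age_mean: float = 46.6
    age_sd: float = 10.9
    height_mean: float = 160.6
    height_sd: float = 8.1
    weight_mean: float = 56.4
    weight_sd: float = 9.3
    male_prev: float = 0.404
    han_chinese_prev: float = 0.966
    smoking_prev: float = 0.105
    drinking_prev: float = 0.051
    cyp2c9_freqs: tuple[float, float, float] = (0.908, 0.087, 0.005)
    vkorc1_freqs: tuple[float, float, float] = (0.010, 0.190, 0.800)
    mhvr_prev: float = 0.789
    mvr_prev: float = 0.810
    avr_prev: float = 0.448
    tvr_prev: float = 0.068
    thrombus_removal_prev: float = 0.086
    hypertension_prev: float = 0.076
    chd_prev: float = 0.012
    diabetes_prev: float = 0.025
    afib_prev: float = 0.323
    hsebo_prev: float = 0.053
    pses_prev: float = 0.009
    increase_inr_prev: float = 0.033
    decrease_inr_prev: float = 0.003
    amiodarone_prev: float = 0.014
    tartine_prev: float = 0.012
    inducer_prev: float = 0.003
    thyroxine_prev: float = 0.003
    fluconazole_prev: float = 0.005
    aspirin_prev: float = 0.012
    dose_model: DoseModel = field(default_factory=DoseModel)

    def prevalence(self, variable: str) -> float:
        if variable == "sex":
            return self.male_prev
        if variable == "bhvr":
            return 1.0 - self.mhvr_prev
        return getattr(self, f"{variable}_prev")

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        for var in ("age", "height", "weight"):
            if getattr(self, f"{var}_mean") <= 0:
                raise ValueError(f"{var}_mean must be positive")
            if getattr(self, f"{var}_sd") < 0:
                raise ValueError(f"{var}_sd must be nonnegative")
        for var in BINARY:
            if var == "bhvr":
                continue
            p = self.prevalence(var)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {var!r} out of [0, 1]: {p}")
        for name, freqs in (("cyp2c9_freqs", self.cyp2c9_freqs), ("vkorc1_freqs", self.vkorc1_freqs)):
            if len(freqs) != 3 or any(f < 0 for f in freqs):
                raise ValueError(f"{name} must be three nonnegative frequencies")
            if abs(sum(freqs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {sum(freqs)}")
        if self.dose_model.noise_sd < 0:
            raise ValueError("dose_model.noise_sd must be nonnegative")
        lo, hi = self.dose_model.dose_bounds
        if not 0 < lo < hi:
            raise ValueError("dose_bounds must satisfy 0 < low < high")

    def with_(self, **updates) -> "GeneratorConfig":
        return replace(self, **updates)


def default_config(n: int = 641, seed: int = 0) -> GeneratorConfig:
    """Generator configuration matching the published cohort's marginals."""
    return GeneratorConfig(n=n, seed=seed)


class Cohort:
    """An ordered patient table with a fixed schema and a dose column.

    Thin wrapper over a :class:`pandas.DataFrame` with the columns of
    :data:`VARIABLES` plus ``dose_mg_day``.  Rows are complete: missing
    values are rejected at construction and on CSV read.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in list(VARIABLES) + [DOSE_COLUMN] if c not in frame.columns]
        if missing:
            raise ValueError(f"cohort table is missing columns: {missing}")
        extra = [c for c in frame.columns if c not in VARIABLES and c != DOSE_COLUMN]
        if extra:
            raise ValueError(f"cohort table has unknown columns: {extra}")
        if frame.isna().any().any():
            bad = frame.columns[frame.isna().any()].tolist()
            raise ValueError(f"missing values are not supported (columns: {bad})")
        frame = frame[list(VARIABLES) + [DOSE_COLUMN]].reset_index(drop=True)
        if len(frame):
            if (frame[DOSE_COLUMN] <= 0).any():
                raise ValueError("doses must be positive")
            for var in BINARY:
                vals = set(frame[var].unique())
                if not vals <= {0, 1}:
                    raise ValueError(f"binary variable {var!r} has values outside {{0,1}}: {sorted(vals)}")
            for var in ORDINAL:
                vals = set(frame[var].unique())
                if not vals <= {0, 1, 2}:
                    raise ValueError(f"genotype {var!r} has codes outside {{0,1,2}}: {sorted(vals)}")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def dose(self) -> np.ndarray:
        return self.frame[DOSE_COLUMN].to_numpy(dtype=float)

    def feature_frame(self, columns: Iterable[str] | None = None, one_hot_genotypes: bool = False) -> pd.DataFrame:
        """Feature matrix (no dose column); optionally one-hot the genotypes."""
        cols = list(columns) if columns is not None else list(VARIABLES)
        unknown = [c for c in cols if c not in VARIABLES]
        if unknown:
            raise KeyError(f"unknown variables: {unknown}")
        X = self.frame[cols].copy()
        if one_hot_genotypes:
            for var, labels in (("cyp2c9", CYP2C9_LABELS), ("vkorc1", VKORC1_LABELS)):
                if var in X.columns:
                    codes = X.pop(var).to_numpy(dtype=int)
                    for level in (1, 2):
                        X[f"{var}_{level}"] = (codes == level).astype(int)
        return X

    def subset(self, indices) -> "Cohort":
        return Cohort(self.frame.iloc[np.asarray(indices)].reset_index(drop=True))

    def to_csv(self, path_or_buf=None) -> str | None:
        return self.frame.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "Cohort":
        # round_trip parsing so write -> read is the identity on doses
        frame = pd.read_csv(path_or_buf, float_precision="round_trip")
        return cls(frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, Cohort) and self.frame.equals(other.frame)


def true_dose(records: pd.DataFrame, model: DoseModel, noise: np.ndarray | None = None) -> np.ndarray:
    """Ground-truth stable dose (mg/day) for each record.

    With ``noise=None`` (or all-zero noise) the map is deterministic; noise
    is a vector of normal deviates applied multiplicatively as ``exp(noise)``.
    """
    n = len(records)
    dose = np.full(n, model.intercept, dtype=float)
    for var, coef in model.linear.items():
        x = records[var].to_numpy(dtype=float)
        dose += coef * (x - model.centers.get(var, 0.0))
    age_c = records["age"].to_numpy(dtype=float) - model.centers.get("age", 45.0)
    t_count = records["vkorc1"].to_numpy(dtype=float)
    dose += model.age_vkorc1_coef * (age_c / 10.0) * t_count
    w = records["weight"].to_numpy(dtype=float)
    dose += model.sqrt_weight_coef * (np.sqrt(w) - np.sqrt(model.centers.get("weight", 56.0)))
    dose = np.clip(dose, *model.dose_bounds)
    if noise is not None:
        dose = np.clip(dose * np.exp(np.asarray(noise, dtype=float)), *model.dose_bounds)
    return dose


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int) -> np.ndarray:
    if sd == 0:
        return np.full(n, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(config: GeneratorConfig | None = None, **overrides) -> Cohort:
    """Draw a synthetic cohort under ``config`` (deterministic per seed)."""
    if config is None:
        config = default_config()
    if overrides:
        config = config.with_(**overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    data: dict[str, np.ndarray] = {}
    for var in CONTINUOUS:
        lo, hi = TRUNCATION_BOUNDS[var]
        data[var] = np.round(
            _truncated_normal(rng, getattr(config, f"{var}_mean"), getattr(config, f"{var}_sd"), lo, hi, n), 1
        )
    for var in BINARY:
        if var == "bhvr":
            continue
        data[var] = rng.binomial(1, config.prevalence(var), size=n)
    data["bhvr"] = 1 - data["mhvr"]
    data["cyp2c9"] = rng.choice(3, size=n, p=np.asarray(config.cyp2c9_freqs) / sum(config.cyp2c9_freqs))
    data["vkorc1"] = rng.choice(3, size=n, p=np.asarray(config.vkorc1_freqs) / sum(config.vkorc1_freqs))
    frame = pd.DataFrame({v: data[v] for v in VARIABLES})
    noise = rng.normal(0.0, config.dose_model.noise_sd, size=n) if config.dose_model.noise_sd > 0 else None
    frame[DOSE_COLUMN] = true_dose(frame, config.dose_model, noise) if n else np.array([])
    return Cohort(frame)


def classify_dose(dose: float) -> str:
    """Dose band: low (<2 mg/day), moderate (2–4 mg/day inclusive), high (>4 mg/day).

    The published band definitions are strict inequalities, leaving doses of
    exactly 2 or 4 mg/day unassigned; both boundaries are closed into the
    moderate band so the partition is exhaustive.
    """
    dose = float(dose)
    if dose <= 0:
        raise ValueError(f"dose must be positive, got {dose}")
    if dose > 4.0:
        return "high"
    if dose >= 2.0:
        return "moderate"
    return "low"


def summarize(cohort: Cohort) -> pd.DataFrame:
    """Baseline-characteristics summary: mean (SD) for continuous, n (%) for categorical."""
    rows = []
    f = cohort.frame
    for var, kind in VARIABLES.items():
        if kind == "continuous":
            rows.append((var, f"{f[var].mean():.1f} ({f[var].std(ddof=1):.1f})"))
        elif kind == "binary":
            k = int(f[var].sum())
            rows.append((var, f"{k} ({100 * k / max(len(f), 1):.1f})"))
        else:
            labels = CYP2C9_LABELS if var == "cyp2c9" else VKORC1_LABELS
            for code, lab in enumerate(labels):
                k = int((f[var] == code).sum())
                rows.append((f"{var} {lab}", f"{k} ({100 * k / max(len(f), 1):.1f})"))
    return pd.DataFrame(rows, columns=["variable", "summary"])
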