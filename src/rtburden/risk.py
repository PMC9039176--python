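"""Cardiovascular risk engine.

Computes age-specific annual transition probabilities for the Markov model:

* 10-year fatal cardiovascular risk from the two-cause (coronary and
  non-coronary) Weibull survival model of the European SCORE project, with
  smoking prevalence entering as an exact two-point mixture over smoker
  status;
* conversion of multi-year risks to constant-rate annual probabilities;
* the linear-in-dose multiplicative excess for radiation exposure,
  ``p * (1 + err_per_gy * mhd)``, applied to the fatal risk before the
  non-fatal scaling so non-fatal events inherit the dose effect;
* assembly of the per-cycle 6x6 transition matrix over the states
  (init_high, init_moderate, init_none, nonfatal_cv, fatal_cv, fatal_noncv).

SCORE coefficients are shipped as a documented plain-text table
(``data/score_coefficients.csv``); the low-risk-region female set is the
default, Belgium being a SCORE low-risk country.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import ParameterSet, ValidationError

STATES = (
    "init_high",
    "init_moderate",
    "init_none",
    "nonfatal_cv",
    "fatal_cv",
    "fatal_noncv",
)
INIT_STATES = {"high": 0, "moderate": 1, "none": 2}
NONFATAL, FATAL_CV, FATAL_NONCV = 3, 4, 5

#: The SCORE functions are calibrated from age 40; younger cohort entrants
#: (the model admits diagnosis at 39) use the age-40 risk.
SCORE_AGE_FLOOR = 40.0


@dataclass(frozen=True)
class RiskProfile:
    """Covariates of the SCORE calculation for one attained age."""

    age: float
    sbp: float
    chol: float
    smoking: float  # prevalence in [0, 1]

    def __post_init__(self) -> None:
        if not 39.0 <= self.age <= 104.0:
            raise ValidationError(f"age {self.age} outside the modelled range 39-104")
        if self.sbp <= 0 or self.chol <= 0:
            raise ValidationError("sbp and chol must be positive")
        if not 0.0 <= self.smoking <= 1.0:
            raise ValidationError("smoking prevalence must lie in [0, 1]")


@dataclass(frozen=True)
class CauseCoefficients:
    alpha: float
    p: float
    beta_chol: float
    beta_sbp: float
    beta_smoker: float

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise ValidationError("Weibull shape p must be positive")


@dataclass(frozen=True)
class ScoreCoefficients:
    chd: CauseCoefficients
    non_chd: CauseCoefficients
    region: str = "low"
    sex: str = "female"


@lru_cache(maxsize=None)
def _read_coefficient_table(path: str | None) -> pd.DataFrame:
    if path is None:
        source = resources.files("rtburden").joinpath("data/score_coefficients.csv")
        with resources.as_file(source) as p:
            return pd.read_csv(p, comment="#")
    return pd.read_csv(path, comment="#")


def load_score_coefficients(
    region: str = "low", sex: str = "female", path: str | Path | None = None
) -> ScoreCoefficients:
    """Load the Weibull coefficient table (default: packaged constants file)."""
    table = _read_coefficient_table(str(path) if path is not None else None)
    sel = table[(table.region == region) & (table.sex == sex)]
    if len(sel) != 2:
        raise ValidationError(f"no coefficient set for region={region!r}, sex={sex!r}")
    by_cause = {
        row.cause: CauseCoefficients(
            row.alpha, row.p, row.beta_chol, row.beta_sbp, row.beta_smoker
        )
        for row in sel.itertuples()
    }
    return ScoreCoefficients(by_cause["chd"], by_cause["non_chd"], region, sex)


def _cause_10yr_risk(coef: CauseCoefficients, age, sbp, chol, smoker):
    """10-year risk of death from one cause for a given smoker status (0/1)."""
    age = np.maximum(np.asarray(age, dtype=float), SCORE_AGE_FLOOR)
    base_now = np.exp(coef.alpha) * (age - 20.0) ** coef.p
    base_10 = np.exp(coef.alpha) * (age - 10.0) ** coef.p
    w = (
        coef.beta_chol * (chol - 6.0)
        + coef.beta_sbp * (sbp - 120.0)
        + coef.beta_smoker * smoker
    )
    # S(age) = S0(age)^exp(w) with S0 = exp(-base); the 10-year conditional
    # survival is S(age + 10) / S(age).
    return 1.0 - np.exp(-(base_10 - base_now) * np.exp(w))


def score_10yr_fatal_cv_risk(
    profile: RiskProfile,
    coef: ScoreCoefficients | None = None,
    combine: str = "survival",
) -> float:
    """Combined 10-year fatal cardiovascular risk for one risk profile.

    ``combine='survival'`` multiplies the two cause-specific conditional
    survivals (default); ``'additive'`` sums the cause-specific risks.
    Smoking prevalence is handled as a mixture:
    risk = prev * risk(smoker) + (1 - prev) * risk(non-smoker).
    """
    coef = coef if coef is not None else load_score_coefficients()
    value = _score_risk(
        profile.age, profile.sbp, profile.chol, profile.smoking, coef, combine
    )
    return float(value)


def _score_risk(age, sbp, chol, smoking, coef: ScoreCoefficients, combine="survival"):
    """Vectorized SCORE risk over arrays of attained ages."""
    if combine not in ("survival", "additive"):
        raise ValidationError(f"unknown combination rule {combine!r}")
    total = 0.0
    for smoker, weight in ((0.0, 1.0 - smoking), (1.0, smoking)):
        if weight == 0.0:
            continue
        r_chd = _cause_10yr_risk(coef.chd, age, sbp, chol, smoker)
        r_non = _cause_10yr_risk(coef.non_chd, age, sbp, chol, smoker)
        if combine == "survival":
            r = 1.0 - (1.0 - r_chd) * (1.0 - r_non)
        else:
            r = r_chd + r_non
        total = total + weight * np.clip(r, 0.0, 1.0 - 1e-12)
    return total


def annualize(p_multi, years: int):
    """Constant-rate annual probability equivalent to a ``years``-year risk."""
    p_multi = np.asarray(p_multi, dtype=float)
    if years < 1:
        raise ValidationError("years must be >= 1")
    if np.any(p_multi < 0.0) or np.any(p_multi >= 1.0):
        raise ValidationError("multi-year probability must lie in [0, 1)")
    result = 1.0 - (1.0 - p_multi) ** (1.0 / years)
    return float(result) if result.ndim == 0 else result


def apply_excess_risk(p, err_per_gy: float, mhd: float):
    """Linear-in-dose multiplicative excess: min(1, p * (1 + err * mhd))."""
    if mhd < 0.0:
        raise ValidationError("mean heart dose must be non-negative")
    p = np.asarray(p, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValidationError("probability must lie in [0, 1]")
    result = np.minimum(1.0, p * (1.0 + err_per_gy * mhd))
    return float(result) if result.ndim == 0 else result


def nonfatal_from_fatal(p_fatal, rr: float):
    """Scale the fatal event probability by the non-fatal rate ratio."""
    p = np.asarray(p_fatal, dtype=float) * rr
    if np.any(p > 1.0):
        raise ValidationError("p_fatal * rr exceeds 1")
    return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class AgeTable:
    """Per-single-year-of-age values (probabilities or weights)."""

    ages: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        values = np.asarray(self.values, dtype=float)
        if ages.shape != values.shape or ages.ndim != 1:
            raise ValidationError("ages and values must be 1-d arrays of equal length")
        if not np.all(np.diff(ages) == 1):
            raise ValidationError("ages must be consecutive single years")
        if np.any(values < 0.0) or np.any(values > 1.0):
            raise ValidationError("values must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)

    def value(self, age):
        """Value(s) at attained age(s); ages must be covered by the table."""
        lo, hi = int(self.ages[0]), int(self.ages[-1])
        if isinstance(age, (int, np.integer)):  # fast scalar path
            if not lo <= age <= hi:
                raise ValidationError(f"age {age} outside table range {lo}-{hi}")
            return float(self.values[age - lo])
        age = np.asarray(age, dtype=int)
        if np.any(age < lo) or np.any(age > hi):
            raise ValidationError(f"age {age} outside table range {lo}-{hi}")
        out = self.values[age - lo]
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "value": self.values})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AgeTable":
        frame = pd.read_csv(path, comment="#")
        return cls(frame["age"].to_numpy(), frame["value"].to_numpy())


def covariates_at_age(ps: ParameterSet, age) -> tuple:
    """(sbp, chol) at attained age: the 40-64 band below 65, 65+ above."""
    age = np.asarray(age)
    sbp = np.where(age >= 65, ps.sbp_65plus, ps.sbp_4064)
    chol = np.where(age >= 65, ps.chol_65plus, ps.chol_4064)
    return sbp, chol


def build_transition_matrix(
    age: int,
    ps: ParameterSet,
    fatal_table: AgeTable,
    background: AgeTable,
    with_excess: bool,
) -> np.ndarray:
    """One-cycle 6x6 transition matrix at a given attained age.

    Each initial-state row applies its stratum's dose (rows share the
    baseline fatal probability from ``fatal_table``); the non-fatal row uses
    the secondary-prevention fatal probability, which deliberately receives
    no dose adjustment; fatal rows are absorbing.
    """
    p_fatal_base = fatal_table.value(age)
    p_bg = background.value(age)
    rr = ps.rr_nonfatal
    matrix = np.zeros((6, 6))
    doses = (ps.mhd_high, ps.mhd_mod, ps.mhd_none)
    for row, mhd in enumerate(doses):
        if mhd < 0.0:
            raise ValidationError("mean heart dose must be non-negative")
        # scalar forms of apply_excess_risk / nonfatal_from_fatal (hot path)
        p_fatal = (
            min(1.0, p_fatal_base * (1.0 + ps.err_per_gy * mhd))
            if with_excess
            else p_fatal_base
        )
        p_nonfatal = p_fatal * rr
        if p_nonfatal > 1.0:
            raise ValidationError("p_fatal * rr exceeds 1")
        events = p_fatal + p_nonfatal + p_bg
        if events > 1.0:
            raise ValidationError(
                f"event probabilities sum to {events} > 1 at age {age}"
            )
        matrix[row, NONFATAL] = p_nonfatal
        matrix[row, FATAL_CV] = p_fatal
        matrix[row, FATAL_NONCV] = p_bg
        matrix[row, row] = 1.0 - events
    events = ps.p_fatal_after_nonfatal + p_bg
    if events > 1.0:
        raise ValidationError(f"non-fatal-state exits sum to {events} > 1 at age {age}")
    matrix[NONFATAL, FATAL_CV] = ps.p_fatal_after_nonfatal
    matrix[NONFATAL, FATAL_NONCV] = p_bg
    matrix[NONFATAL, NONFATAL] = 1.0 - events
    matrix[FATAL_CV, FATAL_CV] = 1.0
    matrix[FATAL_NONCV, FATAL_NONCV] = 1.0
    return matrix


def build_cycle_matrices(
    age_at_diagnosis: int,
    ps: ParameterSet,
    fatal_table: AgeTable,
    background: AgeTable,
    with_excess: bool,
    horizon: int | None = None,
) -> np.ndarray:
    """Stack of per-cycle matrices; cycle t uses attained age ``age + t - 1``."""
    horizon = horizon if horizon is not None else ps.horizon
    return np.stack(
        [
            build_transition_matrix(
                age_at_diagnosis + t - 1, ps, fatal_table, background, with_excess
            )
            for t in range(1, horizon + 1)
        ]
    )
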