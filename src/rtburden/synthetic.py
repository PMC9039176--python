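"""Generators for the age-specific inputs the published summaries imply.

The source material prints only cohort-level summaries: five-year age-group
incidence shares, the cohort-mean annual probability of a fatal non-CV
event, and Dutch-cohort fatal/non-fatal CV event anchors.  This module
produces the per-single-year-of-age tables the model needs by the mechanism
the summaries describe:

* incidence weights: equal split of each five-year group share across its
  single years, renormalized;
* background (non-CV) mortality: a Gompertz-like exponential age curve
  ``q(age) = c * exp(shape * age)`` with ``c`` solved so the incidence-
  weighted mean matches the printed cohort mean;
* CV transition tables: annualized SCORE fatal risk per single year of age
  (no dose adjustment — the excess applies downstream per stratum), with the
  non-fatal table at the fatal table times the event-rate ratio.  An
  optional calibration multiplier can rescale the fatal table to the
  Dutch-cohort anchors under a cumulative or annual interpretation; by
  default no rescaling is applied, since those anchors enter the model only
  through the event-rate ratio.

The emulation reproduces the printed cohort-level means by construction, not
the unpublished single-year values; headline reproduction is therefore
approximate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import brentq

from .parameters import ParameterSet, ValidationError, default_parameters, save_parameters
from .risk import (
    AgeTable,
    ScoreCoefficients,
    _score_risk,
    annualize,
    covariates_at_age,
    load_score_coefficients,
)

#: Published five-year age-group incidence shares ((low, high), share).
TABLE_GROUP_SHARES: tuple[tuple[tuple[int, int], float], ...] = (
    ((39, 44), 0.0636),
    ((45, 49), 0.0940),
    ((50, 54), 0.1239),
    ((55, 59), 0.1267),
    ((60, 64), 0.1410),
    ((65, 69), 0.1426),
    ((70, 74), 0.1231),
    ((75, 79), 0.0984),
    ((80, 84), 0.0867),
)

AGE_MIN, AGE_MAX = 39, 84
#: Tables must cover attained ages through the last cycle.
TABLE_AGE_MAX = 104

#: Default Gompertz log-slope for adult all-cause mortality (per year of age).
DEFAULT_GOMPERTZ_SHAPE = 0.09


@dataclass(frozen=True)
class AgeWeightTable:
    """Cohort incidence weights per single year of age at diagnosis."""

    ages: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        weights = np.asarray(self.weights, dtype=float)
        if ages.shape != weights.shape or ages.ndim != 1:
            raise ValidationError("ages and weights must be 1-d arrays of equal length")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValidationError("weights must sum to 1")
        if np.any(weights < 0.0):
            raise ValidationError("weights must be non-negative")
        if ages[0] < AGE_MIN or ages[-1] > AGE_MAX:
            raise ValidationError(f"ages must span {AGE_MIN}-{AGE_MAX}")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "weights", weights)


def make_incidence_weights(
    group_shares=TABLE_GROUP_SHARES,
) -> AgeWeightTable:
    """Single-year weights from five-year group shares (equal split within)."""
    total = sum(share for _, share in group_shares)
    if abs(total - 1.0) > 0.005:
        raise ValidationError(f"group shares sum to {total}, not 1")
    ages: list[int] = []
    weights: list[float] = []
    for (lo, hi), share in group_shares:
        if hi < lo:
            raise ValidationError(f"malformed age group {lo}-{hi}")
        span = hi - lo + 1
        for age in range(lo, hi + 1):
            ages.append(age)
            weights.append(share / span)
    w = np.asarray(weights)
    return AgeWeightTable(np.asarray(ages), w / w.sum())


def group_shares_from_weights(table: AgeWeightTable) -> dict[tuple[int, int], float]:
    """Re-aggregate single-year weights to the five-year groups."""
    return {
        (lo, hi): float(
            table.weights[(table.ages >= lo) & (table.ages <= hi)].sum()
        )
        for (lo, hi), _ in TABLE_GROUP_SHARES
    }


def make_background_mortality(
    target_mean: float = 0.0181,
    weights: AgeWeightTable | None = None,
    shape: float = DEFAULT_GOMPERTZ_SHAPE,
    age_max: int = TABLE_AGE_MAX,
) -> AgeTable:
    """Exponential (Gompertz-like) non-CV mortality curve, calibrated.

    ``q(age) = c * exp(shape * age)`` with ``c`` solved so the
    incidence-weighted annual probability equals ``target_mean``.
    """
    if not 0.0 < target_mean < 1.0:
        raise ValidationError("target_mean must lie in (0, 1)")
    weights = weights if weights is not None else make_incidence_weights()
    scale = float(np.sum(weights.weights * np.exp(shape * weights.ages)))
    c = target_mean / scale
    ages = np.arange(AGE_MIN, age_max + 1)
    values = c * np.exp(shape * ages)
    if np.any(values >= 1.0):
        raise ValidationError(
            "calibration infeasible: background mortality reaches 1 within the age range"
        )
    return AgeTable(ages, values)


def score_fatal_annual(
    ps: ParameterSet,
    ages: np.ndarray,
    coef: ScoreCoefficients | None = None,
    combine: str = "survival",
) -> np.ndarray:
    """Annualized SCORE fatal CV probability at each attained age."""
    coef = coef if coef is not None else load_score_coefficients()
    sbp, chol = covariates_at_age(ps, ages)
    risk10 = _score_risk(ages, sbp, chol, ps.smoking_rate, coef, combine)
    return annualize(risk10, 10)


def make_cv_transition_tables(
    ps: ParameterSet,
    weights: AgeWeightTable | None = None,
    coef: ScoreCoefficients | None = None,
    combine: str = "survival",
    calibrate: bool = False,
    anchor_interpretation: str = "cumulative",
    follow_up_years: int = 20,
    age_max: int = TABLE_AGE_MAX,
) -> tuple[AgeTable, AgeTable]:
    """(fatal, non-fatal) annual CV event probabilities per attained age.

    The fatal table carries no dose adjustment; the non-fatal table is the
    fatal table scaled by the event-rate ratio, so their quotient is the
    ratio at every age.  With ``calibrate=True`` a single multiplier rescales
    the fatal table so the incidence-weighted fatal probability matches the
    Dutch-cohort anchor mean: either the ``follow_up_years``-cumulative
    probability (``anchor_interpretation='cumulative'``) or the annual
    probability (``'annual'``).
    """
    weights = weights if weights is not None else make_incidence_weights()
    ages = np.arange(AGE_MIN, age_max + 1)
    fatal = score_fatal_annual(ps, ages, coef=coef, combine=combine)
    if calibrate:
        target = ps.p_fatal_cv_mean
        w = weights.weights
        base = fatal[np.searchsorted(ages, weights.ages)]

        if anchor_interpretation == "annual":
            multiplier = target / float(np.sum(w * base))
        elif anchor_interpretation == "cumulative":

            def residual(m: float) -> float:
                cumulative = 1.0 - (1.0 - np.minimum(m * base, 1.0)) ** follow_up_years
                return float(np.sum(w * cumulative)) - target

            multiplier = brentq(residual, 1e-9, 1.0 / float(base.max()), xtol=1e-12)
        else:
            raise ValidationError(
                f"unknown anchor interpretation {anchor_interpretation!r}"
            )
        fatal = np.minimum(fatal * multiplier, 1.0)
    nonfatal = np.minimum(fatal * ps.rr_nonfatal, 1.0)
    return AgeTable(ages, fatal), AgeTable(ages, nonfatal)


@dataclass(frozen=True)
class ModelTables:
    """Bundle of the age-specific inputs consumed by the model."""

    fatal_cv: AgeTable
    nonfatal_cv: AgeTable
    background: AgeTable
    age_weights: AgeWeightTable


def make_model_tables(
    ps: ParameterSet,
    coef: ScoreCoefficients | None = None,
    combine: str = "survival",
    calibrate: bool = False,
    shape: float = DEFAULT_GOMPERTZ_SHAPE,
) -> ModelTables:
    """All generated tables for one parameter set."""
    weights = make_incidence_weights()
    fatal, nonfatal = make_cv_transition_tables(
        ps, weights, coef=coef, combine=combine, calibrate=calibrate
    )
    background = make_background_mortality(
        target_mean=ps.p_fatal_noncv_mean, weights=weights, shape=shape
    )
    return ModelTables(fatal, nonfatal, background, weights)


def make_fixture_config(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a complete, self-consistent config bundle into ``out_dir``.

    Emits the flat parameter YAML (with the decision-tree block) and the
    generated age tables as CSV.  All tables are deterministic; ``seed`` is
    recorded for provenance and reserved for stochastic fixtures.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ps = default_parameters()
    tables = make_model_tables(ps)
    paths = {
        "config": out_dir / "config.yaml",
        "incidence_weights": out_dir / "incidence_weights.csv",
        "background_mortality": out_dir / "background_mortality.csv",
        "fatal_cv": out_dir / "fatal_cv.csv",
        "nonfatal_cv": out_dir / "nonfatal_cv.csv",
    }
    save_parameters(ps, paths["config"])
    from .decision_tree import TreeConfig

    tree = TreeConfig()
    with paths["config"].open("a") as fh:
        fh.write("decision_tree:\n")
        for field_name in ("p_stage0", "rt_stage0", "rt_stage123", "p_left"):
            fh.write(f"  {field_name}: {getattr(tree, field_name)!r}\n")
    np.savetxt(
        paths["incidence_weights"],
        np.column_stack([tables.age_weights.ages, tables.age_weights.weights]),
        fmt=("%d", "%.12g"),
        delimiter=",",
        header="age,value",
        comments="",
    )
    tables.background.to_csv(paths["background_mortality"])
    tables.fatal_cv.to_csv(paths["fatal_cv"])
    tables.nonfatal_cv.to_csv(paths["nonfatal_cv"])
    return paths
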