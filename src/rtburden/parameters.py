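"""Typed registry of every model input.

Each quantity of the cost-utility model — cohort stratification proportions,
mean heart doses, SCORE covariates, transition probabilities, unit costs,
utilities and analysis settings — lives here as a field of
:class:`ParameterSet`, together with distribution metadata used by the
deterministic and probabilistic sensitivity analyses.

Second moments of the parameter distributions are not reported by the source
material; a conventional coefficient of variation of 0.1 is assumed for every
non-fixed parameter and can be overridden per parameter via the
``dispersions`` mapping.

Quantities labelled "calculated" in the source table (the non-fatal/fatal
event-rate ratio, the high/moderate dose ratio, the utility in the non-fatal
CV state) are exposed as derived properties recomputed from their inputs, so
that perturbing an input propagates consistently.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd
import yaml

log = logging.getLogger(__name__)

FAMILIES = ("beta", "gamma", "lognormal", "normal", "fixed")

#: Default coefficient of variation for parameters whose distribution family
#: is known but whose variance is not reported.
DEFAULT_CV = 0.1


class ValidationError(ValueError):
    """A parameter value or combination violates a model invariant."""


@dataclass(frozen=True)
class DistributionSpec:
    """Distribution family plus first two moments (mean, cv) of a parameter."""

    family: str
    mean: float
    cv: float = DEFAULT_CV

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown distribution family {self.family!r}")
        if self.family == "beta" and not 0.0 < self.mean < 1.0:
            raise ValidationError(f"beta mean must lie in (0, 1), got {self.mean}")
        if self.family in ("gamma", "lognormal") and self.mean <= 0.0:
            raise ValidationError(
                f"{self.family} mean must be positive, got {self.mean}"
            )
        if self.family != "fixed" and self.cv < 0.0:
            raise ValidationError(f"cv must be non-negative, got {self.cv}")


@dataclass(frozen=True)
class ParamMeta:
    """Audit metadata for one model input."""

    family: str
    unit: str
    label: str
    kind: str = "value"  # probability | positive | nonneg | integer | value
    printed: float | None = None  # value as printed in the source table
    decimals: int = 4  # printed precision


# Registry of every input parameter: field name -> metadata.  ``printed``
# records the source table's displayed value (used by the audit test); the
# stored default may carry more precision where the table itself derives one
# printed value from another (see p_nonfatal_cv_mean).
PARAM_META: dict[str, ParamMeta] = {
    "p_high": ParamMeta("beta", "probability", "Cohort stratification: high RT exposure", "probability", 0.3680),
    "p_mod": ParamMeta("beta", "probability", "Cohort stratification: moderate RT exposure", "probability", 0.3383),
    "p_none": ParamMeta("beta", "probability", "Cohort stratification: no RT exposure", "probability", 0.2937),
    "mhd_high": ParamMeta("lognormal", "Gy", "Mean heart dose: high RT exposure", "nonneg", 3.6000),
    "mhd_mod": ParamMeta("fixed", "Gy", "Mean heart dose: moderate RT exposure", "nonneg", 1.9000),
    "mhd_none": ParamMeta("fixed", "Gy", "Mean heart dose: no RT exposure", "nonneg", 0.0000),
    "err_per_gy": ParamMeta("lognormal", "1/Gy", "Excess risk ratio for cardiotoxicity", "nonneg", 0.0410),
    "sbp_4064": ParamMeta("normal", "mmHg", "Systolic blood pressure 40-64 years", "positive", 116.0847),
    "sbp_65plus": ParamMeta("normal", "mmHg", "Systolic blood pressure 65+ years", "positive", 136.2094),
    "chol_4064": ParamMeta("normal", "mmol/L", "Total cholesterol 40-64 years", "positive", 5.1832),
    "chol_65plus": ParamMeta("normal", "mmol/L", "Total cholesterol 65+ years", "positive", 5.4144),
    "smoking_rate": ParamMeta("beta", "probability", "Rate of smokers in a cohort of breast cancer survivors", "probability", 0.0951),
    "p_fatal_cv_mean": ParamMeta("beta", "probability", "Probability of fatal CV event in breast cancer survivors", "probability", 0.0427),
    "p_nonfatal_cv_mean": ParamMeta("beta", "probability", "Probability of non-fatal CV event in breast cancer survivors", "probability", 0.1175),
    "p_fatal_after_nonfatal": ParamMeta("beta", "probability", "Probability of fatal CV event after non-fatal CV event", "probability", 0.0115),
    "p_fatal_noncv_mean": ParamMeta("beta", "probability", "Probability for fatal non-CV event in breast cancer survivors", "probability", 0.0181),
    "activity_rate": ParamMeta("gamma", "probability", "Work-related activity rate for women", "probability", 0.6490),
    "p_perm_disability": ParamMeta("beta", "probability", "Probability of permanent disability after non-fatal CV event", "probability", 0.0394),
    "p_temp_sickleave": ParamMeta("fixed", "probability", "Probability of temporarily sick leave after non-fatal CV event", "probability", 0.9616),
    "sickdays_y1": ParamMeta("gamma", "days/year", "Mean sick leave days during first year after non-fatal CV event", "nonneg", 48.0000),
    "sickdays_later": ParamMeta("gamma", "days/year", "Mean sick leave days in following years after non-fatal CV event", "nonneg", 25.0000),
    "wage_annual": ParamMeta("gamma", "EUR/year", "Annual wage for women aged 40-65 years, anno 2021", "nonneg", 55559.7500),
    "wage_daily": ParamMeta("gamma", "EUR/day", "Daily wage for women aged 40-65 years, anno 2021", "nonneg", 252.3000),
    "primary_y1": ParamMeta("gamma", "EUR", "Primary care costs during first year after non-fatal CV event", "nonneg", 54.1200),
    "primary_later": ParamMeta("gamma", "EUR", "Primary care costs in following years after non-fatal CV event", "nonneg", 94.7100),
    "outpatient_y1": ParamMeta("gamma", "EUR", "Outpatient care costs during first year after non-fatal CV event", "nonneg", 196.3300),
    "outpatient_later": ParamMeta("gamma", "EUR", "Outpatient care costs in following years after non-fatal CV event", "nonneg", 155.7800),
    "ae_event": ParamMeta("gamma", "EUR", "Prehospital A&E care costs after non-fatal and fatal CV event", "nonneg", 455.6200),
    "inpatient_event": ParamMeta("gamma", "EUR", "Inpatient care costs after non-fatal CV event", "nonneg", 4547.5100),
    "pharma_annual": ParamMeta("gamma", "EUR/year", "Pharmaceutical costs after non-fatal CV event", "nonneg", 149.0882),
    "u_initial": ParamMeta("beta", "utility", "Utility for women in the initial state(s)", "probability", 0.7700),
    "disutility_ref": ParamMeta("fixed", "utility", "Disutility for chronic CV disorders (reference cohort)", "probability", 0.1100),
    "qol_ref": ParamMeta("lognormal", "utility", "Quality of life in reference cohort (all ages)", "probability", 0.9100),
    "discount_costs": ParamMeta("fixed", "1/year", "Annual discount rate on costs", "nonneg", 0.03, 2),
    "discount_outcomes": ParamMeta("fixed", "1/year", "Annual discount rate on outcomes", "nonneg", 0.015, 3),
    "horizon": ParamMeta("fixed", "cycles", "Analytic time horizon", "integer", 20, 0),
    "retirement_age": ParamMeta("fixed", "years", "Retirement age (human-capital window)", "integer", 65, 0),
}

#: Parameters eligible for sensitivity analysis (the source-table inputs;
#: excludes analysis settings and quantities derived from other rows).
TABLE1_PARAMS: tuple[str, ...] = tuple(
    name
    for name in PARAM_META
    if name not in ("discount_costs", "discount_outcomes", "horizon", "retirement_age")
)

_STRATUM_PROPS = ("p_high", "p_mod", "p_none")


@dataclass(frozen=True)
class ParameterSet:
    """All model inputs with their deterministic (base-case) values.

    Defaults reproduce the published base case; construct via keyword
    overrides, :func:`load_parameters`, or :meth:`replace`.
    """

    p_high: float = 0.3680
    p_mod: float = 0.3383
    p_none: float = 0.2937
    mhd_high: float = 3.6000
    mhd_mod: float = 1.9000
    mhd_none: float = 0.0000
    err_per_gy: float = 0.0410
    sbp_4064: float = 116.0847
    sbp_65plus: float = 136.2094
    chol_4064: float = 5.1832
    chol_65plus: float = 5.4144
    smoking_rate: float = 0.0951
    p_fatal_cv_mean: float = 0.0427
    # 0.0427 * 2.7515: carries the precision implied by the published
    # calculated event-rate ratio; displays as 0.1175 at table precision.
    p_nonfatal_cv_mean: float = 0.11748905
    p_fatal_after_nonfatal: float = 0.0115
    p_fatal_noncv_mean: float = 0.0181
    activity_rate: float = 0.6490
    p_perm_disability: float = 0.0394
    p_temp_sickleave: float = 0.9616
    sickdays_y1: float = 48.0
    sickdays_later: float = 25.0
    wage_annual: float = 55559.75
    wage_daily: float = 252.30
    primary_y1: float = 54.12
    primary_later: float = 94.71
    outpatient_y1: float = 196.33
    outpatient_later: float = 155.78
    ae_event: float = 455.62
    inpatient_event: float = 4547.51
    pharma_annual: float = 149.0882
    u_initial: float = 0.7700
    disutility_ref: float = 0.1100
    qol_ref: float = 0.9100
    discount_costs: float = 0.03
    discount_outcomes: float = 0.015
    horizon: int = 20
    retirement_age: int = 65
    dispersions: Mapping[str, float] = field(default_factory=dict)

    # -- derived ("calculated") quantities ---------------------------------
    @property
    def rr_nonfatal(self) -> float:
        """Non-fatal CV events per fatal CV event (rate ratio)."""
        return self.p_nonfatal_cv_mean / self.p_fatal_cv_mean

    @property
    def mhd_ratio(self) -> float:
        """Mean heart dose ratio, high vs moderate exposure."""
        return self.mhd_high / self.mhd_mod

    @property
    def u_nonfatal_cv(self) -> float:
        """Utility in the non-fatal CV state (proportional-decrement rule)."""
        from .economics import cv_event_utility

        return cv_event_utility(self.u_initial, self.disutility_ref, self.qol_ref)

    # -- validation --------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, meta in PARAM_META.items():
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValidationError(f"{name} is not finite")
            if meta.kind == "probability" and not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name}={value} outside [0, 1]")
            if meta.kind == "positive" and value <= 0.0:
                raise ValidationError(f"{name}={value} must be positive")
            if meta.kind in ("nonneg", "integer") and value < 0.0:
                raise ValidationError(f"{name}={value} must be non-negative")
        if abs(self.p_high + self.p_mod + self.p_none - 1.0) > 1e-9:
            raise ValidationError(
                "stratum proportions p_high + p_mod + p_none must sum to 1, got "
                f"{self.p_high + self.p_mod + self.p_none!r}"
            )
        if self.horizon < 1:
            raise ValidationError("horizon must be at least one cycle")
        if self.p_fatal_cv_mean <= 0.0:
            raise ValidationError("p_fatal_cv_mean must be positive (rate ratio)")
        if not 0.0 < self.qol_ref <= 1.0:
            raise ValidationError("qol_ref must lie in (0, 1]")
        if not 0.0 <= self.disutility_ref < self.qol_ref:
            raise ValidationError("disutility_ref must lie in [0, qol_ref)")
        if self.disutility_ref > 0.0 and not self.u_nonfatal_cv < self.u_initial:
            raise ValidationError("u_nonfatal_cv must be below u_initial")
        for name, cv in self.dispersions.items():
            if name not in PARAM_META:
                raise ValidationError(f"dispersion for unknown parameter {name!r}")
            if cv < 0.0:
                raise ValidationError(f"dispersion for {name} must be >= 0")

    # -- helpers -----------------------------------------------------------
    def replace(self, **changes: Any) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def value(self, name: str) -> float:
        if name not in PARAM_META:
            raise ValidationError(f"unknown parameter {name!r}")
        return getattr(self, name)

    def distribution(self, name: str) -> DistributionSpec:
        """Sampling distribution of one parameter (for the PSA)."""
        meta = PARAM_META[name]
        cv = float(self.dispersions.get(name, DEFAULT_CV))
        if meta.family == "fixed":
            cv = 0.0
        return DistributionSpec(meta.family, float(getattr(self, name)), cv)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_META}


def default_parameters() -> ParameterSet:
    """The deterministic base case."""
    return ParameterSet()


def scale_parameter(ps: ParameterSet, name: str, factor: float) -> ParameterSet:
    """Return a copy of ``ps`` with one parameter multiplied by ``factor``.

    Probabilities exceeding 1 after scaling are clipped to 1 with a logged
    warning.  Scaling one stratum proportion renormalizes the three
    proportions so they keep summing to one.
    """
    if name not in PARAM_META:
        raise ValidationError(f"unknown parameter {name!r}")
    if factor <= 0.0:
        raise ValidationError(f"scale factor must be positive, got {factor}")
    meta = PARAM_META[name]
    value = getattr(ps, name) * factor
    if meta.kind == "probability" and value > 1.0:
        log.warning("scaling %s by %g exceeds 1; clipping to 1", name, factor)
        value = 1.0
    if meta.kind == "integer":
        value = int(round(value))
    changes: dict[str, Any] = {name: value}
    if name in _STRATUM_PROPS:
        props = {p: getattr(ps, p) for p in _STRATUM_PROPS}
        props[name] = value
        total = sum(props.values())
        log.info("renormalizing stratum proportions after scaling %s", name)
        changes = {p: v / total for p, v in props.items()}
    return ps.replace(**changes)


_RESERVED_KEYS = ("decision_tree", "tables", "dispersions")


def load_parameters(path: str | Path) -> ParameterSet:
    """Load a parameter configuration (flat YAML/JSON mapping).

    Unspecified fields fall back to defaults; unknown keys and invariant
    violations raise :class:`ValidationError`.  The ``decision_tree``,
    ``tables`` and ``dispersions`` sections are reserved for the respective
    consumers.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ValidationError(f"config {path} must be a mapping")
    overrides: dict[str, Any] = {}
    for key, value in raw.items():
        if key in ("decision_tree", "tables"):
            continue
        if key == "dispersions":
            overrides["dispersions"] = dict(value)
            continue
        if key not in PARAM_META:
            raise ValidationError(f"unknown parameter {key!r} in {path}")
        overrides[key] = value
    return ParameterSet(**overrides)


def save_parameters(ps: ParameterSet, path: str | Path) -> None:
    """Write a flat YAML mapping that :func:`load_parameters` round-trips."""
    doc: dict[str, Any] = ps.as_dict()
    if ps.dispersions:
        doc["dispersions"] = dict(ps.dispersions)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def parameter_dictionary(ps: ParameterSet | None = None) -> pd.DataFrame:
    """Tabular parameter dictionary (name, value, unit, description, family)."""
    ps = ps if ps is not None else default_parameters()
    rows = [
        {
            "name": name,
            "value": getattr(ps, name),
            "unit": meta.unit,
            "description": meta.label,
            "family": meta.family,
            "cv": ps.distribution(name).cv,
        }
        for name, meta in PARAM_META.items()
    ]
    return pd.DataFrame(rows)
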