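"""Costing and health-outcome valuation of a cohort trace.

Direct medical costs comprise primary care, outpatient care, prehospital
A&E, inpatient care and pharmaceuticals.  The A&E, inpatient and first-year
follow-up costs attach to new non-fatal events (the trace's tunnel year);
subsequent years in the non-fatal state accrue the following-year follow-up
and the annually recurring pharmaceutical cost; directly fatal events incur
the prehospital A&E cost once.

Indirect costs follow the human-capital approach on gross wages: temporary
sick leave (first-year and following-year day counts), permanent disability
and premature cardiovascular death trigger wage losses for the economically
active fraction until retirement age.  Annuities are discounted from the
event cycle at the cost discount rate and are not truncated at the analytic
horizon (the human-capital loss runs to retirement).

Outcomes are quality-adjusted life years: initial-state occupancy at the
baseline utility, non-fatal-state occupancy at the proportionally
decremented utility, death at zero.  Costs discount at ``discount_costs``
and outcomes at ``discount_outcomes``; the first event year (cycle 1) is
undiscounted, i.e. the discount exponent for cycle t is t - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ParameterSet, ValidationError

DIRECT_CATEGORIES = ("primary", "outpatient", "ae", "inpatient", "pharma")
INDIRECT_CATEGORIES = ("temporary_sick_leave", "permanent_disability", "premature_death")


@dataclass(frozen=True)
class CostBreakdown:
    """Discounted cost per woman, split by category."""

    direct: dict[str, float]
    indirect: dict[str, float]

    @property
    def direct_total(self) -> float:
        return float(sum(self.direct.values()))

    @property
    def indirect_total(self) -> float:
        return float(sum(self.indirect.values()))

    @property
    def total(self) -> float:
        return self.direct_total + self.indirect_total


@dataclass(frozen=True)
class OutcomeSummary:
    """Discounted QALYs and life years per woman."""

    qalys: float
    life_years: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.qalys <= self.life_years + 1e-9:
            raise ValidationError("0 <= qalys <= life_years violated")


def discount_factor(rate: float, t):
    """Present-value factor (1 + rate)^(-t) for a cycle offset t."""
    if rate < 0.0:
        raise ValidationError("discount rate must be non-negative")
    t = np.asarray(t, dtype=float)
    out = (1.0 + rate) ** (-t)
    return float(out) if out.ndim == 0 else out


def cv_event_utility(u_base: float, disutility_ref: float, qol_ref: float) -> float:
    """Utility after a non-fatal CV event: proportional decrement transfer.

    The relative disutility observed in a reference cohort
    (``disutility_ref / qol_ref``) is applied to the local baseline utility.
    """
    if not 0.0 < qol_ref <= 1.0:
        raise ValidationError("qol_ref must lie in (0, 1]")
    if not 0.0 <= disutility_ref < qol_ref:
        raise ValidationError("disutility_ref must lie in [0, qol_ref)")
    return u_base * (1.0 - disutility_ref / qol_ref)


def _cycles(trace) -> np.ndarray:
    return np.arange(1, trace.horizon + 1)


def _direct_arrays(trace, ps: ParameterSet) -> dict[str, np.ndarray]:
    """Per-cycle undiscounted direct costs by category (cycles 1..H)."""
    t = _cycles(trace)
    new_nf = trace.new_nonfatal[t]
    later = trace.nonfatal_later[t]
    new_fatal_direct = trace.new_fatal_direct[t]
    return {
        "primary": new_nf * ps.primary_y1 + later * ps.primary_later,
        "outpatient": new_nf * ps.outpatient_y1 + later * ps.outpatient_later,
        "ae": (new_nf + new_fatal_direct) * ps.ae_event,
        "inpatient": new_nf * ps.inpatient_event,
        "pharma": (new_nf + later) * ps.pharma_annual,
    }


def _annuity_years(ps: ParameterSet, event_age) -> np.ndarray:
    """Whole years of wage lost from an event at a given attained age."""
    return np.maximum(0.0, ps.retirement_age - np.asarray(event_age, dtype=float))


def _annuity_factor(rate: float, years: np.ndarray) -> np.ndarray:
    """Present value, at the event cycle, of a unit annuity over ``years``."""
    years = np.asarray(years, dtype=float)
    if rate == 0.0:
        return years
    v = 1.0 / (1.0 + rate)
    return (1.0 - v**years) / (1.0 - v)


def _indirect_arrays(
    trace, ps: ParameterSet, age_at_start: float
) -> dict[str, np.ndarray]:
    """Per-cycle undiscounted human-capital losses (annuities pre-discounted
    to their event cycle)."""
    t = _cycles(trace)
    event_age = age_at_start + t - 1
    working = (event_age < ps.retirement_age).astype(float)
    temp = (
        working
        * ps.activity_rate
        * ps.p_temp_sickleave
        * ps.wage_daily
        * (
            trace.new_nonfatal[t] * ps.sickdays_y1
            + trace.nonfatal_later[t] * ps.sickdays_later
        )
    )
    years = _annuity_years(ps, event_age) * working
    annuity = ps.wage_annual * _annuity_factor(ps.discount_costs, years)
    return {
        "temporary_sick_leave": temp,
        "permanent_disability": trace.new_nonfatal[t]
        * ps.activity_rate
        * ps.p_perm_disability
        * annuity,
        "premature_death": trace.new_fatal_cv[t] * ps.activity_rate * annuity,
    }


def _sum_streams(
    streams: dict[str, np.ndarray], rate: float, horizon: int, discounted: bool
) -> dict[str, float]:
    df = discount_factor(rate, np.arange(horizon)) if discounted else 1.0
    return {cat: float(np.sum(values * df)) for cat, values in streams.items()}


def direct_costs(trace, ps: ParameterSet, discounted: bool = True) -> dict[str, float]:
    """Aggregate direct costs per woman, by category."""
    return _sum_streams(
        _direct_arrays(trace, ps), ps.discount_costs, trace.horizon, discounted
    )


def indirect_costs(
    trace, ps: ParameterSet, age_at_start: float, discounted: bool = True
) -> dict[str, float]:
    """Aggregate indirect costs per woman, by component."""
    return _sum_streams(
        _indirect_arrays(trace, ps, age_at_start),
        ps.discount_costs,
        trace.horizon,
        discounted,
    )


def cost_breakdown(trace, ps: ParameterSet, age_at_start: float) -> CostBreakdown:
    return CostBreakdown(
        direct=direct_costs(trace, ps),
        indirect=indirect_costs(trace, ps, age_at_start),
    )


def cost_streams(trace, ps: ParameterSet, age_at_start: float) -> pd.DataFrame:
    """Tidy per-cycle cost export: (cycle, category, undiscounted, discounted)."""
    t = _cycles(trace)
    df = discount_factor(ps.discount_costs, t - 1)
    streams = _direct_arrays(trace, ps) | _indirect_arrays(trace, ps, age_at_start)
    rows = [
        {
            "cycle": int(cycle),
            "category": cat,
            "undiscounted": float(values[i]),
            "discounted": float(values[i] * df[i]),
        }
        for cat, values in streams.items()
        for i, cycle in enumerate(t)
    ]
    return pd.DataFrame(rows)


def qalys(trace, ps: ParameterSet, discounted: bool = True) -> OutcomeSummary:
    """Discounted QALYs and life years accrued over cycles 1..horizon."""
    t = _cycles(trace)
    df = (
        discount_factor(ps.discount_outcomes, t - 1)
        if discounted
        else np.ones_like(t, dtype=float)
    )
    alive = trace.occ_init[t] + trace.occ_nonfatal[t]
    utility = (
        trace.occ_init[t] * ps.u_initial + trace.occ_nonfatal[t] * ps.u_nonfatal_cv
    )
    return OutcomeSummary(
        qalys=float((utility * df).sum()), life_years=float((alive * df).sum())
    )
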