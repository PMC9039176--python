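"""Comparator runs and incremental aggregation.

Two situations are compared for every single year of age at diagnosis and
every exposure stratum: one in which the radiation-induced excess
cardiovascular risk is applied (``with_excess=True``) and one in which it is
not.  Per-age incremental costs, QALYs and event counts are the arm
differences; the cohort aggregate weights the per-age results by the
age-specific incidence weights.  Costs and QALYs are reported per woman,
event counts per 1000 women.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .decision_tree import (
    StratumWeights,
    TreeConfig,
    rt_only_weights,
    stage_scenario_weights,
    stratify,
)
from .economics import CostBreakdown, OutcomeSummary, cost_breakdown, qalys
from .markov import count_events, run_cohort
from .parameters import ParameterSet, ValidationError
from .risk import INIT_STATES, build_cycle_matrices
from .synthetic import AgeWeightTable, ModelTables, make_incidence_weights, make_model_tables

SCENARIOS = ("base", "rt_only", "stage0_only", "stages123_only")


@dataclass(frozen=True)
class ArmResult:
    """Stratum-weighted deliverables of one comparator arm at one age."""

    costs: CostBreakdown
    outcomes: OutcomeSummary
    nonfatal_events: float  # expected events per woman
    fatal_cv_events: float


@dataclass(frozen=True)
class IncrementalResult:
    """Arm differences; costs/QALYs per woman, events per 1000 women."""

    d_cost_total: float
    d_cost_direct: float
    d_cost_indirect: float
    d_qalys: float
    d_nonfatal: float
    d_fatal_cv: float
    nonfatal_with: float
    nonfatal_without: float
    fatal_with: float
    fatal_without: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def run_comparator(
    ps: ParameterSet,
    weights: StratumWeights,
    age: int,
    tables: ModelTables,
    with_excess: bool,
) -> ArmResult:
    """Run every occupied stratum at one diagnosis age and weight the results."""
    matrices = build_cycle_matrices(
        age, ps, tables.fatal_cv, tables.background, with_excess
    )
    direct: dict[str, float] = {}
    indirect: dict[str, float] = {}
    total_qalys = total_ly = nonfatal = fatal = 0.0
    for stratum, proportion, _ in weights.items():
        if proportion == 0.0:
            continue
        trace = run_cohort(INIT_STATES[stratum], matrices)
        costs = cost_breakdown(trace, ps, age)
        for cat, value in costs.direct.items():
            direct[cat] = direct.get(cat, 0.0) + proportion * value
        for cat, value in costs.indirect.items():
            indirect[cat] = indirect.get(cat, 0.0) + proportion * value
        outcome = qalys(trace, ps)
        total_qalys += proportion * outcome.qalys
        total_ly += proportion * outcome.life_years
        events = count_events(trace)
        nonfatal += proportion * events.expected_nonfatal
        fatal += proportion * events.expected_fatal_cv
    return ArmResult(
        costs=CostBreakdown(direct=direct, indirect=indirect),
        outcomes=OutcomeSummary(qalys=total_qalys, life_years=total_ly),
        nonfatal_events=nonfatal,
        fatal_cv_events=fatal,
    )


def incremental(
    ps: ParameterSet, weights: StratumWeights, age: int, tables: ModelTables
) -> IncrementalResult:
    """Per-age incremental result: excess-risk arm minus comparator arm."""
    on = run_comparator(ps, weights, age, tables, with_excess=True)
    off = run_comparator(ps, weights, age, tables, with_excess=False)
    return IncrementalResult(
        d_cost_total=on.costs.total - off.costs.total,
        d_cost_direct=on.costs.direct_total - off.costs.direct_total,
        d_cost_indirect=on.costs.indirect_total - off.costs.indirect_total,
        d_qalys=on.outcomes.qalys - off.outcomes.qalys,
        d_nonfatal=(on.nonfatal_events - off.nonfatal_events) * 1000.0,
        d_fatal_cv=(on.fatal_cv_events - off.fatal_cv_events) * 1000.0,
        nonfatal_with=on.nonfatal_events * 1000.0,
        nonfatal_without=off.nonfatal_events * 1000.0,
        fatal_with=on.fatal_cv_events * 1000.0,
        fatal_without=off.fatal_cv_events * 1000.0,
    )


def aggregate(
    per_age: dict[int, IncrementalResult], table: AgeWeightTable
) -> IncrementalResult:
    """Incidence-weighted mean of per-age incremental results."""
    missing = [int(a) for a in table.ages if int(a) not in per_age]
    if missing:
        raise ValidationError(f"no per-age result for ages {missing}")
    acc = {f.name: 0.0 for f in fields(IncrementalResult)}
    for age, weight in zip(table.ages, table.weights):
        result = per_age[int(age)]
        for name in acc:
            acc[name] += float(weight) * float(getattr(result, name))
    return IncrementalResult(**acc)


def per_age_incremental(
    ps: ParameterSet,
    weights: StratumWeights,
    tables: ModelTables,
    ages=None,
) -> dict[int, IncrementalResult]:
    ages = ages if ages is not None else tables.age_weights.ages
    return {int(age): incremental(ps, weights, int(age), tables) for age in ages}


def weights_from_parameters(ps: ParameterSet) -> StratumWeights:
    """The base-case stratification carried by the parameter set."""
    return StratumWeights(
        p_high=ps.p_high,
        p_mod=ps.p_mod,
        p_none=ps.p_none,
        mhd_high=ps.mhd_high,
        mhd_mod=ps.mhd_mod,
    )


def base_case(
    ps: ParameterSet,
    tables: ModelTables | None = None,
    weights: StratumWeights | None = None,
) -> tuple[IncrementalResult, dict[int, IncrementalResult]]:
    """Full base-case pipeline from a parameter set.

    Regenerates the age-specific tables from ``ps`` (so sensitivity analyses
    propagate through the SCORE inputs), runs every age, and aggregates.
    """
    tables = tables if tables is not None else make_model_tables(ps)
    weights = weights if weights is not None else weights_from_parameters(ps)
    per_age = per_age_incremental(ps, weights, tables)
    return aggregate(per_age, tables.age_weights), per_age


def run_scenario(
    ps: ParameterSet,
    scenario: str,
    tree: TreeConfig | None = None,
    tables: ModelTables | None = None,
) -> IncrementalResult:
    """Base case under one of the deterministic scenario stratifications."""
    if scenario not in SCENARIOS:
        raise ValidationError(f"unknown scenario {scenario!r}")
    tree = tree if tree is not None else TreeConfig()
    if scenario == "base":
        weights = weights_from_parameters(ps)
    elif scenario == "rt_only":
        weights = rt_only_weights(weights_from_parameters(ps))
    else:
        weights = stage_scenario_weights(
            tree, scenario, mhd_high=ps.mhd_high, mhd_mod=ps.mhd_mod
        )
    result, _ = base_case(ps, tables=tables, weights=weights)
    return result


def per_age_frame(per_age: dict[int, IncrementalResult]) -> pd.DataFrame:
    """Tidy per-age incremental results (one row per diagnosis age)."""
    rows = [{"age": age, **res.as_dict()} for age, res in sorted(per_age.items())]
    return pd.DataFrame(rows)


def age_group_events(
    per_age: dict[int, IncrementalResult],
    table: AgeWeightTable,
    groups=None,
) -> pd.DataFrame:
    """Expected events per 1000 women of the cohort, by five-year age group.

    Each group row is the incidence-weighted contribution of its single
    years to the total cohort (so the rows sum to the cohort totals).
    """
    from .synthetic import TABLE_GROUP_SHARES

    groups = groups if groups is not None else [g for g, _ in TABLE_GROUP_SHARES]
    weight_of = dict(zip((int(a) for a in table.ages), table.weights))
    rows = []
    for lo, hi in groups:
        acc = dict.fromkeys(
            ("share", "nonfatal_with", "nonfatal_without", "fatal_with", "fatal_without"),
            0.0,
        )
        for age in range(lo, hi + 1):
            w = weight_of.get(age, 0.0)
            if w == 0.0 or age not in per_age:
                continue
            res = per_age[age]
            acc["share"] += w
            for key in ("nonfatal_with", "nonfatal_without", "fatal_with", "fatal_without"):
                acc[key] += w * getattr(res, key)
        rows.append(
            {
                "age_group": f"{lo}-{hi}",
                "share": acc["share"],
                "nonfatal_with": acc["nonfatal_with"],
                "nonfatal_without": acc["nonfatal_without"],
                "d_nonfatal": acc["nonfatal_with"] - acc["nonfatal_without"],
                "fatal_with": acc["fatal_with"],
                "fatal_without": acc["fatal_without"],
                "d_fatal": acc["fatal_with"] - acc["fatal_without"],
            }
        )
    frame = pd.DataFrame(rows)
    totals = frame.drop(columns="age_group").sum()
    totals["age_group"] = "total"
    return pd.concat([frame, totals.to_frame().T], ignore_index=True)[frame.columns]
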