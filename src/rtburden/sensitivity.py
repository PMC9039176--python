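"""Deterministic (tornado) and probabilistic sensitivity analysis.

The one-way analysis reruns the full base-case aggregate with each parameter
at 70% and 130% of its base value and records the spread of the incremental
cost and QALY results.  The probabilistic analysis jointly resamples all
non-fixed inputs from moment-matched distributions (beta, gamma, log-normal,
normal), recomputes the derived quantities and age tables per draw, and
reruns the aggregate.  Parameters are sampled independently; the three
stratum proportions are resampled as a unit and renormalized to preserve
their sum.  Each parameter owns an RNG stream derived from the master seed,
so adding a parameter does not perturb the draws of the others.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .comparative import IncrementalResult, base_case
from .parameters import (
    TABLE1_PARAMS,
    DistributionSpec,
    ParameterSet,
    ValidationError,
    scale_parameter,
)

log = logging.getLogger(__name__)

Evaluator = Callable[[ParameterSet], IncrementalResult]

_STRATUM_PROPS = ("p_high", "p_mod", "p_none")


def _default_evaluate(ps: ParameterSet) -> IncrementalResult:
    result, _ = base_case(ps)
    return result


@dataclass(frozen=True)
class TornadoEntry:
    """One-way result of perturbing a single parameter both ways."""

    name: str
    low_input: float
    high_input: float
    d_cost_low: float
    d_cost_high: float
    d_qalys_low: float
    d_qalys_high: float

    @property
    def span_cost(self) -> float:
        return abs(self.d_cost_high - self.d_cost_low)

    @property
    def span_qalys(self) -> float:
        return abs(self.d_qalys_high - self.d_qalys_low)


def one_way_dsa(
    ps: ParameterSet,
    names: Sequence[str] | None = None,
    proportion: float = 0.30,
    evaluate: Evaluator | None = None,
) -> list[TornadoEntry]:
    """Tornado entries for each parameter, sorted by cost span (descending)."""
    if not 0.0 <= proportion < 1.0:
        raise ValidationError("proportion must lie in [0, 1)")
    names = tuple(names) if names is not None else TABLE1_PARAMS
    evaluate = evaluate if evaluate is not None else _default_evaluate
    base_result = evaluate(ps) if proportion == 0.0 else None
    entries = []
    for name in names:
        if proportion == 0.0:
            low_ps = high_ps = scale_parameter(ps, name, 1.0)
            low = high = base_result
        else:
            low_ps = scale_parameter(ps, name, 1.0 - proportion)
            high_ps = scale_parameter(ps, name, 1.0 + proportion)
            low = evaluate(low_ps)
            high = evaluate(high_ps)
        entries.append(
            TornadoEntry(
                name=name,
                low_input=low_ps.value(name),
                high_input=high_ps.value(name),
                d_cost_low=low.d_cost_total,
                d_cost_high=high.d_cost_total,
                d_qalys_low=low.d_qalys,
                d_qalys_high=high.d_qalys,
            )
        )
    entries.sort(key=lambda e: e.span_cost, reverse=True)
    return entries


def tornado_frame(
    entries: Sequence[TornadoEntry], outcome: str = "cost", top_k: int | None = 8
) -> pd.DataFrame:
    """Sorted tornado table for one outcome ('cost' or 'qalys')."""
    if outcome not in ("cost", "qalys"):
        raise ValidationError(f"unknown tornado outcome {outcome!r}")
    key = "span_cost" if outcome == "cost" else "span_qalys"
    ordered = sorted(entries, key=lambda e: getattr(e, key), reverse=True)
    if top_k is not None:
        ordered = ordered[:top_k]
    return pd.DataFrame(
        [
            {
                "parameter": e.name,
                "low_input": e.low_input,
                "high_input": e.high_input,
                "d_cost_low": e.d_cost_low,
                "d_cost_high": e.d_cost_high,
                "d_qalys_low": e.d_qalys_low,
                "d_qalys_high": e.d_qalys_high,
                "span": getattr(e, key),
            }
            for e in ordered
        ]
    )


def sample_parameter(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """One moment-matched draw from a parameter's distribution.

    The standard deviation is ``cv * mean``; a zero cv (or the fixed family)
    returns the mean.  Beta moment matching requires the implied variance to
    be feasible on (0, 1).
    """
    mean, sd = spec.mean, spec.cv * abs(spec.mean)
    if spec.family == "fixed" or sd == 0.0:
        return float(mean)
    if spec.family == "normal":
        return float(rng.normal(mean, sd))
    if spec.family == "gamma":
        shape = 1.0 / spec.cv**2
        return float(rng.gamma(shape, mean / shape))
    if spec.family == "lognormal":
        sigma2 = np.log1p(spec.cv**2)
        mu = np.log(mean) - sigma2 / 2.0
        return float(rng.lognormal(mu, np.sqrt(sigma2)))
    if spec.family == "beta":
        var = sd**2
        bound = mean * (1.0 - mean)
        if var >= bound:
            raise ValidationError(
                f"beta moment matching infeasible: var {var} >= {bound}"
            )
        nu = bound / var - 1.0
        return float(rng.beta(mean * nu, (1.0 - mean) * nu))
    raise ValidationError(f"unknown family {spec.family!r}")


@dataclass(frozen=True)
class PsaResult:
    """Draws and summary of a probabilistic sensitivity analysis."""

    draws: pd.DataFrame  # columns d_cost, d_qalys
    seed: int | None
    n: int
    n_rejected: int

    @property
    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for col in ("d_cost", "d_qalys"):
            values = self.draws[col].to_numpy()
            out[col] = {
                "mean": float(values.mean()),
                "min": float(values.min()),
                "max": float(values.max()),
                "variance": float(values.var(ddof=1)) if len(values) > 1 else 0.0,
                "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
            }
        return out


def _parameter_stream(master_seed: int | None, name: str) -> np.random.Generator:
    """Independent, name-keyed RNG stream derived from the master seed."""
    tag = zlib.crc32(name.encode()) & 0x7FFFFFFF
    entropy = [tag] if master_seed is None else [int(master_seed), tag]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _sampled_names(ps: ParameterSet, names: Sequence[str]) -> list[str]:
    return [name for name in names if ps.distribution(name).cv > 0.0]


def draw_parameter_set(
    ps: ParameterSet, streams: dict[str, np.random.Generator]
) -> ParameterSet:
    """One joint draw; stratum proportions are renormalized as a unit."""
    changes = {name: sample_parameter(ps.distribution(name), rng) for name, rng in streams.items()}
    drawn_props = {p: changes.get(p, getattr(ps, p)) for p in _STRATUM_PROPS}
    total = sum(drawn_props.values())
    if total <= 0.0:
        raise ValidationError("degenerate stratum proportion draw")
    for p, value in drawn_props.items():
        if p in changes or total != 1.0:
            changes[p] = value / total
    return ps.replace(**changes)


def run_psa(
    ps: ParameterSet,
    n: int = 1000,
    seed: int | None = None,
    names: Sequence[str] | None = None,
    evaluate: Evaluator | None = None,
    max_rejections: int = 1000,
) -> PsaResult:
    """Monte Carlo resampling of all non-fixed inputs, ``n`` full model runs."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    names = _sampled_names(ps, tuple(names) if names is not None else TABLE1_PARAMS)
    evaluate = evaluate if evaluate is not None else _default_evaluate
    streams = {name: _parameter_stream(seed, name) for name in names}
    records = []
    rejected = 0
    for _ in range(n):
        while True:
            try:
                candidate = draw_parameter_set(ps, streams)
                result = evaluate(candidate)
                break
            except ValidationError as err:
                rejected += 1
                if rejected > max_rejections:
                    raise ValidationError(
                        f"PSA rejected more than {max_rejections} draws"
                    ) from err
                log.debug("rejected PSA draw: %s", err)
        records.append({"d_cost": result.d_cost_total, "d_qalys": result.d_qalys})
    if rejected:
        log.info("PSA resampled %d infeasible draws", rejected)
    return PsaResult(draws=pd.DataFrame(records), seed=seed, n=n, n_rejected=rejected)
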