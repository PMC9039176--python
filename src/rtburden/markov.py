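"""Markov cohort engine: expected-value propagation and a microsimulation oracle.

The cohort enters one initial exposure state with mass one and is propagated
through per-cycle transition matrices for the analytic horizon.  The trace
records, per cycle, the state occupancy, the inflow of new non-fatal events
(a one-cycle tunnel separating first-year from subsequent-year occupancy,
needed because first-year costs differ), and the inflow into the fatal
cardiovascular state split by origin.

Cycle convention: the diagnosis year is cycle 0 with no events; events occur
in cycles 1..horizon.  No half-cycle correction is applied (the conventional
whole-cycle cohort bookkeeping); an optional correction is available for the
aggregate accumulators in :mod:`rtburden.economics`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ValidationError
from .risk import FATAL_CV, FATAL_NONCV, INIT_STATES, NONFATAL, STATES


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy and event inflows, cycles 0..horizon."""

    occupancy: np.ndarray  # (horizon+1, 6)
    new_nonfatal: np.ndarray  # (horizon+1,)
    new_fatal_direct: np.ndarray  # inflow into fatal_cv from initial states
    new_fatal_from_nonfatal: np.ndarray  # inflow into fatal_cv from nonfatal_cv

    def __post_init__(self) -> None:
        if not np.allclose(self.occupancy.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("occupancy rows must sum to 1")
        if np.any(self.occupancy < -1e-12):
            raise ValidationError("occupancy must be non-negative")

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def new_fatal_cv(self) -> np.ndarray:
        """Total inflow into the fatal CV state (both origins)."""
        return self.new_fatal_direct + self.new_fatal_from_nonfatal

    @property
    def occ_init(self) -> np.ndarray:
        return self.occupancy[:, :3].sum(axis=1)

    @property
    def occ_nonfatal(self) -> np.ndarray:
        return self.occupancy[:, NONFATAL]

    @property
    def nonfatal_first_year(self) -> np.ndarray:
        """Tunnel: occupancy in the first year after a non-fatal event."""
        return self.new_nonfatal

    @property
    def nonfatal_later(self) -> np.ndarray:
        """Occupancy in subsequent years of the non-fatal state."""
        return self.occ_nonfatal - self.new_nonfatal


@dataclass(frozen=True)
class EventCounts:
    """Expected events per cohort member (or per 1000 if scaled)."""

    expected_nonfatal: float
    expected_fatal_cv: float
    horizon: int
    se_nonfatal: float = 0.0
    se_fatal_cv: float = 0.0


def _start_index(start: int | str) -> int:
    if isinstance(start, str):
        if start in INIT_STATES:
            return INIT_STATES[start]
        if start in STATES:
            return STATES.index(start)
        raise ValidationError(f"unknown start state {start!r}")
    if not 0 <= int(start) < len(STATES):
        raise ValidationError(f"start state index {start} out of range")
    return int(start)


def run_cohort(
    start: int | str, matrices: np.ndarray, horizon: int | None = None
) -> CohortTrace:
    """Propagate a unit cohort through per-cycle transition matrices."""
    matrices = np.asarray(matrices, dtype=float)
    if matrices.ndim != 3 or matrices.shape[1:] != (6, 6):
        raise ValidationError("matrices must have shape (cycles, 6, 6)")
    horizon = horizon if horizon is not None else matrices.shape[0]
    if matrices.shape[0] < horizon:
        raise ValidationError(
            f"{matrices.shape[0]} matrices cannot cover horizon {horizon}"
        )
    occupancy = np.zeros((horizon + 1, 6))
    occupancy[0, _start_index(start)] = 1.0
    new_nonfatal = np.zeros(horizon + 1)
    new_fatal_direct = np.zeros(horizon + 1)
    new_fatal_from_nonfatal = np.zeros(horizon + 1)
    for t in range(1, horizon + 1):
        matrix = matrices[t - 1]
        prev = occupancy[t - 1]
        occupancy[t] = prev @ matrix
        inflow_sources = np.arange(6) != NONFATAL
        new_nonfatal[t] = prev[inflow_sources] @ matrix[inflow_sources, NONFATAL]
        new_fatal_direct[t] = prev[:3] @ matrix[:3, FATAL_CV]
        new_fatal_from_nonfatal[t] = prev[NONFATAL] * matrix[NONFATAL, FATAL_CV]
    return CohortTrace(occupancy, new_nonfatal, new_fatal_direct, new_fatal_from_nonfatal)


def count_events(
    trace: CohortTrace, per_1000: bool = False, direct_fatal_only: bool = False
) -> EventCounts:
    """Expected cumulative events over the trace horizon."""
    scale = 1000.0 if per_1000 else 1.0
    fatal = (
        trace.new_fatal_direct if direct_fatal_only else trace.new_fatal_cv
    ).sum()
    return EventCounts(
        expected_nonfatal=float(trace.new_nonfatal.sum() * scale),
        expected_fatal_cv=float(fatal * scale),
        horizon=trace.horizon,
    )


def microsim_oracle(
    start: int | str,
    matrices: np.ndarray,
    horizon: int | None = None,
    n: int = 100_000,
    seed: int | None = None,
) -> EventCounts:
    """Individual-level simulation used as an independent check on the trace.

    Samples ``n`` trajectories by per-cycle categorical draws and returns
    empirical per-individual event counts with binomial standard errors.
    """
    matrices = np.asarray(matrices, dtype=float)
    horizon = horizon if horizon is not None else matrices.shape[0]
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    states = np.full(n, _start_index(start), dtype=np.int64)
    entered_nonfatal = np.zeros(n, dtype=bool)
    entered_fatal = np.zeros(n, dtype=bool)
    for t in range(horizon):
        rows = matrices[t][states]  # (n, 6)
        cum = np.cumsum(rows, axis=1)
        u = rng.random(n)
        new_states = (u[:, None] > cum).sum(axis=1)
        entered_nonfatal |= (new_states == NONFATAL) & (states != NONFATAL)
        entered_fatal |= (new_states == FATAL_CV) & (states != FATAL_CV)
        states = new_states
    p_nf = entered_nonfatal.mean()
    p_f = entered_fatal.mean()
    return EventCounts(
        expected_nonfatal=float(p_nf),
        expected_fatal_cv=float(p_f),
        horizon=horizon,
        se_nonfatal=float(np.sqrt(p_nf * (1 - p_nf) / n)),
        se_fatal_cv=float(np.sqrt(p_f * (1 - p_f) / n)),
    )
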