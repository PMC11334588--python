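"""Interim decision engine: evaluate accrued 2x2 data against boundaries.

Participant-level accrual data are a table with columns ``order`` (the
recruitment sequence, 1..N), ``reference`` (1 = diseased by the reference
standard) and ``index`` (1 = index test positive), optionally ``day`` when
results become available in batches.  At each scheduled interim the engine
cross-tabulates the accrued records, computes failure counts (false
negatives for the sensitivity endpoint, false positives for specificity),
compares them with the exact group sequential boundary at the *observed*
group size, and combines the two endpoint decisions into a study decision.

Decisions are made on integer failure counts, never on rounded percentages:
``failures >= r_g`` is equivalent to ``estimate <= 1 - r_g/n_g``, so an
estimate exactly equal to its boundary stops the study.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .boundaries import (
    DASH,
    UNATTAINABLE,
    Boundary,
    Count,
    DesignError,
    EndpointDesign,
    EndpointLabel,
    efficacy_boundary_count,
    futility_boundary_count,
)
from .design import DTADesign, FutilityRule, realized_stage_sizes

__all__ = [
    "AccuracyTable",
    "DataError",
    "Decision",
    "EndpointResult",
    "InterimResult",
    "evaluate_interim",
    "monitor",
    "read_participants",
    "tabulate",
    "write_participants",
]


class DataError(ValueError):
    """Raised when participant data are malformed."""


class Decision(str, enum.Enum):
    STOP_FUTILITY = "stop_futility"
    STOP_EFFICACY = "stop_efficacy"
    CONTINUE = "continue"
    NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class AccuracyTable:
    """2x2 cross-tabulation of index test vs reference standard."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise DataError("2x2 counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def n_total(self) -> int:
        return self.n_pos + self.n_neg

    @property
    def sensitivity(self) -> Optional[Fraction]:
        return Fraction(self.tp, self.n_pos) if self.n_pos else None

    @property
    def specificity(self) -> Optional[Fraction]:
        return Fraction(self.tn, self.n_neg) if self.n_neg else None


@dataclass(frozen=True)
class EndpointResult:
    """One endpoint's state at an interim analysis."""

    label: EndpointLabel
    n: int
    failures: int
    estimate: Optional[Fraction]  # accuracy scale; None when n == 0
    futility_count: Optional[Count]
    boundary: Optional[Boundary]  # accuracy scale; DASH when unattainable
    efficacy_count: Optional[Count]
    decision: Decision


@dataclass(frozen=True)
class InterimResult:
    """Decisions at one analysis (interim or final)."""

    stage: int
    is_final: bool
    n_total: int
    sens: EndpointResult
    spec: EndpointResult
    overall: Decision


_RECORD_COLUMNS = ("order", "reference", "index")


def _normalize_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise DataError(f"participant data missing column(s): {missing}")
    recs = records.sort_values("order").reset_index(drop=True)
    order = recs["order"].to_numpy()
    if len(order) and not np.array_equal(order, np.arange(1, len(order) + 1)):
        raise DataError("participant 'order' must be unique and contiguous from 1")
    return recs


def read_participants(path: Union[str, Path]) -> pd.DataFrame:
    """Read a participant CSV (columns order, reference, index[, day]).

    Values outside {0, 1} in the reference or index columns are rejected
    with the offending row numbers.
    """
    try:
        recs = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise DataError(f"cannot read participant CSV {path}: {exc}") from exc
    missing = [c for c in _RECORD_COLUMNS if c not in recs.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")
    for col in ("reference", "index"):
        values = recs[col]
        bad = ~values.isin((0, 1))
        if bad.any():
            rows = [int(i) + 2 for i in recs.index[bad][:10]]  # +2: header + 1-base
            raise DataError(
                f"{path}: column '{col}' must be 0/1; invalid values at row(s) {rows}"
            )
    return _normalize_records(recs)


def write_participants(records: pd.DataFrame, path: Union[str, Path]) -> None:
    records.to_csv(path, index=False)


def tabulate(records: pd.DataFrame, upto: int) -> AccuracyTable:
    """Cross-tabulate the first ``upto`` records (by recruitment order)."""
    if upto > len(records):
        raise DataError(f"upto={upto} exceeds the {len(records)} available records")
    head = records.iloc[:upto]
    ref = head["reference"].to_numpy(dtype=bool)
    idx = head["index"].to_numpy(dtype=bool)
    return AccuracyTable(
        tp=int((ref & idx).sum()),
        fn=int((ref & ~idx).sum()),
        tn=int((~ref & ~idx).sum()),
        fp=int((~ref & idx).sum()),
    )


def _evaluate_endpoint(
    endpoint: EndpointDesign, n: int, failures: int
) -> EndpointResult:
    if n == 0:
        return EndpointResult(
            label=endpoint.label,
            n=0,
            failures=0,
            estimate=None,
            futility_count=None,
            boundary=None,
            efficacy_count=None,
            decision=Decision.NOT_EVALUABLE,
        )
    r = futility_boundary_count(n, endpoint)
    a = efficacy_boundary_count(n, endpoint) if endpoint.efficacy is not None else None
    boundary: Boundary = DASH if r is UNATTAINABLE else Fraction(n - int(r), n)
    if r is not UNATTAINABLE and failures >= int(r):
        decision = Decision.STOP_FUTILITY
    elif a is not None and a is not UNATTAINABLE and failures <= int(a):
        decision = Decision.STOP_EFFICACY
    else:
        decision = Decision.CONTINUE
    return EndpointResult(
        label=endpoint.label,
        n=n,
        failures=failures,
        estimate=Fraction(n - failures, n),
        futility_count=r,
        boundary=boundary,
        efficacy_count=a,
        decision=decision,
    )


def _combine(design: DTADesign, sens: EndpointResult, spec: EndpointResult) -> Decision:
    evaluable = [e for e in (sens, spec) if e.decision is not Decision.NOT_EVALUABLE]
    if not evaluable:
        return Decision.CONTINUE
    futile = [e.decision is Decision.STOP_FUTILITY for e in evaluable]
    if design.futility_rule is FutilityRule.EITHER:
        if any(futile):
            return Decision.STOP_FUTILITY
    elif all(futile):
        return Decision.STOP_FUTILITY
    # Efficacy always requires every evaluable endpoint to qualify.
    if all(e.decision is Decision.STOP_EFFICACY for e in evaluable):
        return Decision.STOP_EFFICACY
    return Decision.CONTINUE


def evaluate_interim(
    design: DTADesign,
    table: AccuracyTable,
    stage_index: int = 1,
    is_final: bool = False,
) -> InterimResult:
    """Evaluate one analysis from a 2x2 table of the accrued data.

    Boundaries are computed at the observed endpoint-group sizes (which may
    overshoot the planned milestones) while staying anchored to the planned
    final group sizes.  An endpoint with no accrued participants is
    NOT_EVALUABLE and never contributes to stopping.
    """
    sens = _evaluate_endpoint(design.sens_endpoint, table.n_pos, table.fn)
    spec = _evaluate_endpoint(design.spec_endpoint, table.n_neg, table.fp)
    return InterimResult(
        stage=stage_index,
        is_final=is_final,
        n_total=table.n_total,
        sens=sens,
        spec=spec,
        overall=_combine(design, sens, spec),
    )


def monitor(design: DTADesign, records: pd.DataFrame) -> list[InterimResult]:
    """Run the full monitoring schedule over an accrual stream.

    Walks the scheduled interim points (and the final target) in order,
    evaluating each stage that the accrual reaches; once an analysis stops
    the study, later scheduled analyses are not evaluated.  Stages the data
    never reach produce no result.
    """
    recs = _normalize_records(records)
    n_points = len(design.schedule_points) + 1
    results: list[InterimResult] = []
    for stage in range(1, n_points + 1):
        cut = realized_stage_sizes(design, recs, stage)
        if cut is None:
            break
        table = tabulate(recs, cut.position)
        result = evaluate_interim(
            design, table, stage_index=stage, is_final=(stage == n_points)
        )
        results.append(result)
        if result.overall in (Decision.STOP_FUTILITY, Decision.STOP_EFFICACY):
            break
    return results
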