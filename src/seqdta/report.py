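"""Rendering of boundary tables, decision reports and plot geometry.

Estimates and boundaries are displayed as percentages.  Display rounding is
half-to-even computed exactly over rationals, matching the convention of the
published tables (e.g. the boundary 1 - 7/8 = 12.5% prints as "12%", while
the estimate 7/8 = 87.5% prints as "88%"); a boundary that would fall below
0% prints as a dash.  Decisions are always made upstream on integer failure
counts -- rendering never alters them.
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .boundaries import (
    DASH,
    UNATTAINABLE,
    Boundary,
    Count,
    boundary_set,
)
from .design import DTADesign, project_group_sizes
from .interim import Decision, EndpointLabel, EndpointResult, InterimResult

__all__ = [
    "boundary_rectangles",
    "format_boundary",
    "format_percent",
    "percent",
    "read_report",
    "render_text",
    "report_table",
    "write_report",
]


def _as_fraction(value: Union[Fraction, float, int]) -> Fraction:
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    # Recover the underlying rational from a float computed as a count ratio.
    return Fraction(value).limit_denominator(10**9)


def percent(value: Union[Fraction, float, int], precision: int = 0) -> float:
    """Exact half-to-even percent rounding of a proportion.

    ``precision`` is the number of decimal places kept on the percent scale
    (0 for table style "52%", 1 for "88.5%").
    """
    if precision not in (0, 1):
        raise ValueError(f"precision must be 0 or 1, got {precision}")
    scale = 10**precision
    q = _as_fraction(value) * 100 * scale
    floor = q.numerator // q.denominator
    rem = q - floor
    if rem > Fraction(1, 2) or (rem == Fraction(1, 2) and floor % 2 == 1):
        floor += 1
    return floor / scale


def format_percent(value: Union[Fraction, float, int], precision: int = 0) -> str:
    return f"{percent(value, precision):.{precision}f}%"


def format_boundary(
    boundary: Union[Boundary, None], precision: int = 0
) -> str:
    """Render an accuracy-scale boundary; dashes mark impossible stopping."""
    if boundary is DASH or boundary is UNATTAINABLE or boundary is None:
        return "-"
    return format_percent(boundary, precision)


_DECISION_TEXT = {
    Decision.CONTINUE: "Continue",
    Decision.STOP_FUTILITY: "Stop for futility",
    Decision.STOP_EFFICACY: "Stop for efficacy",
    Decision.NOT_EVALUABLE: "Not evaluable",
}


def _decision_text(decision: Decision, is_final: bool) -> str:
    if decision is Decision.CONTINUE and is_final:
        return "No termination"
    return _DECISION_TEXT[decision]


def _count_cell(count: Optional[Count]):
    if count is None or count is UNATTAINABLE:
        return pd.NA
    return int(count)


def report_table(results: Sequence[InterimResult], precision: int = 0) -> pd.DataFrame:
    """One row per reached analysis, with exact counts and display columns.

    Integer columns (group sizes, failure counts, boundary counts) carry the
    full state of each :class:`InterimResult`; the formatted percent and
    decision-text columns mirror the presentation of published boundary
    tables.
    """
    rows = []
    for res in results:
        row: dict = {
            "stage": res.stage,
            "is_final": res.is_final,
            "n_total": res.n_total,
        }
        for prefix, ep in (("sens", res.sens), ("spec", res.spec)):
            row[f"{prefix}_n"] = ep.n
            row[f"{prefix}_failures"] = ep.failures
            row[f"{prefix}_futility_count"] = _count_cell(ep.futility_count)
            row[f"{prefix}_efficacy_count"] = _count_cell(ep.efficacy_count)
            row[f"{prefix}_decision"] = ep.decision.value
            row[f"{prefix}_estimate"] = (
                "" if ep.estimate is None else format_percent(ep.estimate, precision)
            )
            row[f"{prefix}_boundary"] = (
                "" if ep.n == 0 else format_boundary(ep.boundary, precision)
            )
            row[f"{prefix}_decision_text"] = _decision_text(ep.decision, res.is_final)
        row["overall_decision"] = res.overall.value
        row["decision_text"] = _decision_text(res.overall, res.is_final)
        rows.append(row)
    columns = [
        "stage",
        "is_final",
        "n_total",
        "sens_n",
        "sens_failures",
        "sens_futility_count",
        "sens_efficacy_count",
        "sens_estimate",
        "sens_boundary",
        "sens_decision",
        "sens_decision_text",
        "spec_n",
        "spec_failures",
        "spec_futility_count",
        "spec_efficacy_count",
        "spec_estimate",
        "spec_boundary",
        "spec_decision",
        "spec_decision_text",
        "overall_decision",
        "decision_text",
    ]
    df = pd.DataFrame(rows, columns=columns)
    for col in df.columns:
        if col.endswith(("_futility_count", "_efficacy_count")):
            df[col] = df[col].astype("Int64")
    return df


def render_text(df: pd.DataFrame) -> str:
    """Aligned plain-text rendering in the style of a published table."""
    if df.empty:
        header = ["N (N_pos)", "Sensitivity (boundary)", "Specificity (boundary)", "Decision"]
        return "  ".join(header)
    display = pd.DataFrame(
        {
            "N (N_pos)": [
                f"{r.n_total} ({r.sens_n})" for r in df.itertuples()
            ],
            "Sensitivity (boundary)": [
                f"{r.sens_estimate} ({r.sens_boundary})" if r.sens_n else "-"
                for r in df.itertuples()
            ],
            "Specificity (boundary)": [
                f"{r.spec_estimate} ({r.spec_boundary})" if r.spec_n else "-"
                for r in df.itertuples()
            ],
            "Sens decision": df["sens_decision_text"],
            "Spec decision": df["spec_decision_text"],
            "Decision": df["decision_text"],
        }
    )
    return display.to_string(index=False)


def write_report(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, index=False)


def _endpoint_from_row(row, prefix: str, label: EndpointLabel) -> EndpointResult:
    n = int(getattr(row, f"{prefix}_n"))
    failures = int(getattr(row, f"{prefix}_failures"))
    r = getattr(row, f"{prefix}_futility_count")
    a = getattr(row, f"{prefix}_efficacy_count")
    decision = Decision(getattr(row, f"{prefix}_decision"))
    if n == 0:
        return EndpointResult(label, 0, 0, None, None, None, None, decision)
    futility_count: Count = UNATTAINABLE if pd.isna(r) else int(r)
    boundary: Boundary = (
        DASH if futility_count is UNATTAINABLE else Fraction(n - int(futility_count), n)
    )
    efficacy_count = None if pd.isna(a) else int(a)
    return EndpointResult(
        label=label,
        n=n,
        failures=failures,
        estimate=Fraction(n - failures, n),
        futility_count=futility_count,
        boundary=boundary,
        efficacy_count=efficacy_count,
        decision=decision,
    )


def read_report(path: Union[str, Path]) -> list[InterimResult]:
    """Re-parse a CSV report into the interim results it was written from.

    Exact by construction: the CSV stores the integer counts, and estimates
    and boundaries are reconstructed as rationals from them.

    Note: an efficacy count that was UNATTAINABLE round-trips as ``None``
    (indistinguishable in the CSV from efficacy being disabled); all other
    fields are recovered exactly.
    """
    df = pd.read_csv(path)
    for col in df.columns:
        if col.endswith(("_futility_count", "_efficacy_count")):
            df[col] = df[col].astype("Int64")
    results = []
    for row in df.itertuples():
        results.append(
            InterimResult(
                stage=int(row.stage),
                is_final=bool(row.is_final),
                n_total=int(row.n_total),
                sens=_endpoint_from_row(row, "sens", EndpointLabel.FNR),
                spec=_endpoint_from_row(row, "spec", EndpointLabel.FPR),
                overall=Decision(row.overall_decision),
            )
        )
    return results


def boundary_rectangles(
    design: DTADesign,
    results: Optional[Sequence[InterimResult]] = None,
    precision: int = 1,
) -> pd.DataFrame:
    """Continue-region rectangles per stage, on the percent accuracy scale.

    The rectangle at each stage is the region strictly above both futility
    boundaries, with upper edges at 100%; a dashed boundary spans the full
    axis (lower edge at 0%).  Without ``results`` the rectangles use the
    planned (projected) group sizes; passing monitor results draws them at
    the observed group sizes, as in a post-hoc study figure.  Later stages
    nest inside earlier ones.  Intended as plotting geometry for external
    tools.
    """

    def _low(b: Optional[Boundary]) -> float:
        return 0.0 if (b is DASH or b is None) else percent(b, precision)

    rows = []
    if results is not None:
        for res in results:
            rows.append(
                {
                    "stage": res.stage,
                    "is_final": res.is_final,
                    "n_pos": res.sens.n,
                    "n_neg": res.spec.n,
                    "sens_low": _low(res.sens.boundary),
                    "sens_high": 100.0,
                    "spec_low": _low(res.spec.boundary),
                    "spec_high": 100.0,
                }
            )
        return pd.DataFrame(rows)
    groups = project_group_sizes(design)
    sens_bs = boundary_set(design.sens_endpoint)
    spec_bs = boundary_set(design.spec_endpoint)
    for g in range(len(groups.positives)):
        rows.append(
            {
                "stage": g + 1,
                "is_final": g == len(groups.positives) - 1,
                "n_pos": groups.positives[g],
                "n_neg": groups.negatives[g],
                "sens_low": _low(sens_bs.accuracy_boundaries[g]),
                "sens_high": 100.0,
                "spec_low": _low(spec_bs.accuracy_boundaries[g]),
                "spec_high": 100.0,
            }
        )
    return pd.DataFrame(rows)
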