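"""Bivariate monitoring plans for diagnostic test accuracy studies.

A :class:`DTADesign` couples two endpoint plans -- one for sensitivity
(monitored as the false-negative rate over disease-positive participants)
and one for specificity (false-positive rate over disease-negatives) --
with an accrual schedule.  Interim analyses are scheduled either by the
total number of participants recruited (``BY_TOTAL``) or by the number of
disease-positive cases observed (``BY_POSITIVES``); the assumed prevalence
converts between the two and provides the planned endpoint-group sizes that
anchor the boundaries.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .boundaries import (
    DesignError,
    EfficacySpec,
    EndpointDesign,
    EndpointLabel,
)

__all__ = [
    "ConfigError",
    "DTADesign",
    "FutilityRule",
    "GroupSizes",
    "ScheduleMode",
    "StageCut",
    "expected_total_participants",
    "load_design",
    "make_design",
    "design_to_dict",
    "design_from_dict",
    "project_group_sizes",
    "realized_stage_sizes",
    "reestimate_target",
]


class ScheduleMode(str, enum.Enum):
    BY_TOTAL = "by_total"
    BY_POSITIVES = "by_positives"


class FutilityRule(str, enum.Enum):
    """How per-endpoint futility decisions combine into a study decision.

    ``EITHER`` (the default) stops the study when either sensitivity or
    specificity crosses its futility boundary; ``BOTH`` requires both.
    Early stopping for efficacy always requires both endpoints.
    """

    EITHER = "either"
    BOTH = "both"


class ConfigError(DesignError):
    """Raised when a serialized design document is invalid."""


def _round_half_up(x: Fraction) -> int:
    return math.floor(x + Fraction(1, 2))


def _prev_fraction(prevalence: float) -> Fraction:
    # Prevalence is interpreted as the decimal the user wrote (0.35 means
    # exactly 35%), so projections round deterministically.
    return Fraction(str(prevalence))


@dataclass(frozen=True)
class DTADesign:
    """A full sensitivity + specificity interim monitoring plan."""

    prevalence: float
    schedule_mode: ScheduleMode
    schedule_points: tuple[int, ...]
    target: int
    sens_endpoint: EndpointDesign
    spec_endpoint: EndpointDesign
    futility_rule: FutilityRule = FutilityRule.EITHER

    def __post_init__(self) -> None:
        object.__setattr__(self, "schedule_mode", ScheduleMode(self.schedule_mode))
        object.__setattr__(self, "futility_rule", FutilityRule(self.futility_rule))
        object.__setattr__(
            self, "schedule_points", tuple(int(p) for p in self.schedule_points)
        )
        if not 0 < self.prevalence < 1:
            raise DesignError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if self.target < 1:
            raise DesignError(f"target must be >= 1, got {self.target}")
        pts = self.schedule_points
        if any(p < 1 for p in pts):
            raise DesignError("schedule points must be positive")
        if any(b <= a for a, b in zip(pts, pts[1:])):
            raise DesignError(f"schedule points must be strictly increasing: {pts}")
        if pts and pts[-1] >= self.target:
            raise DesignError(
                f"schedule points must all be below the target ({self.target}): {pts}"
            )
        if self.sens_endpoint.label is not EndpointLabel.FNR:
            raise DesignError("sens_endpoint must monitor the FNR")
        if self.spec_endpoint.label is not EndpointLabel.FPR:
            raise DesignError("spec_endpoint must monitor the FPR")


@dataclass(frozen=True)
class GroupSizes:
    """Planned cumulative endpoint-group sizes, final stage included."""

    positives: tuple[int, ...]
    negatives: tuple[int, ...]


@dataclass(frozen=True)
class StageCut:
    """Observed group sizes at the accrual cut of a reached stage."""

    n_pos: int
    n_neg: int
    n_total: int
    position: int  # 1-based index of the last record included


def _projected_groups(
    prevalence: float, mode: ScheduleMode, points: Sequence[int]
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    prev = _prev_fraction(prevalence)
    positives: list[int] = []
    negatives: list[int] = []
    for point in points:
        if mode is ScheduleMode.BY_TOTAL:
            pos = _round_half_up(point * prev)
            positives.append(pos)
            negatives.append(point - pos)
        else:
            positives.append(int(point))
            negatives.append(_round_half_up(point * (1 - prev) / prev))
    return tuple(positives), tuple(negatives)


def project_group_sizes(design: DTADesign) -> GroupSizes:
    """Planned positive/negative group sizes at each interim and the final.

    Under ``BY_TOTAL`` the positives at a scheduled point are
    ``round(point * prevalence)`` (half away from zero) and negatives the
    remainder; under ``BY_POSITIVES`` the points are the positives and
    negatives are projected through the odds ``(1 - prevalence)/prevalence``.
    Projections are planning quantities: at analysis time observed group
    sizes replace them.
    """
    points = design.schedule_points + (design.target,)
    pos, neg = _projected_groups(design.prevalence, design.schedule_mode, points)
    return GroupSizes(positives=pos, negatives=neg)


def make_design(
    prevalence: float,
    schedule_mode: Union[str, ScheduleMode],
    schedule_points: Sequence[int],
    target: int,
    sens_p0: float,
    spec_p0: float,
    alpha: float = 0.05,
    futility_rule: Union[str, FutilityRule] = FutilityRule.EITHER,
    sens_efficacy: Optional[EfficacySpec] = None,
    spec_efficacy: Optional[EfficacySpec] = None,
) -> DTADesign:
    """Build a :class:`DTADesign`, deriving endpoint plans from the schedule.

    The per-endpoint stage sizes and final anchors are the projected group
    sizes under the assumed prevalence; the anchors fix the boundary
    construction for the whole study.
    """
    mode = ScheduleMode(schedule_mode)
    points = tuple(int(p) for p in schedule_points)
    all_points = points + (int(target),)
    pos, neg = _projected_groups(prevalence, mode, all_points)
    sens = EndpointDesign(
        label=EndpointLabel.FNR,
        p0=sens_p0,
        stage_sizes=pos[:-1],
        anchor_size=pos[-1],
        alpha=alpha,
        efficacy=sens_efficacy,
    )
    spec = EndpointDesign(
        label=EndpointLabel.FPR,
        p0=spec_p0,
        stage_sizes=neg[:-1],
        anchor_size=neg[-1],
        alpha=alpha,
        efficacy=spec_efficacy,
    )
    return DTADesign(
        prevalence=prevalence,
        schedule_mode=mode,
        schedule_points=points,
        target=int(target),
        sens_endpoint=sens,
        spec_endpoint=spec,
        futility_rule=FutilityRule(futility_rule),
    )


def _day_end_positions(records: pd.DataFrame) -> "pd.Index":
    # Positions (1-based) at which accrual data become available for
    # analysis.  Without a `day` column every record is its own batch.
    if "day" in records.columns:
        day = records["day"].to_numpy()
        is_end = np.append(day[:-1] != day[1:], True)
        return pd.Index(np.nonzero(is_end)[0] + 1)
    return pd.Index(range(1, len(records) + 1))


def realized_stage_sizes(
    design: DTADesign, records: pd.DataFrame, stage_index: int
) -> Optional[StageCut]:
    """Observed group sizes at a scheduled stage, or ``None`` if unreached.

    The cut is the first accrual position (batch boundary, when records
    carry a ``day`` column) at or beyond the scheduled point, so the
    analysis may include more participants than the milestone -- overshoot
    is retained, not truncated.  ``stage_index`` counts from 1; the index
    one past the last interim denotes the final analysis at the target.
    """
    points = design.schedule_points + (design.target,)
    if not 1 <= stage_index <= len(points):
        raise DesignError(f"stage_index must be in 1..{len(points)}")
    point = points[stage_index - 1]
    ref = records["reference"].to_numpy()
    ends = _day_end_positions(records)
    cum_pos = ref.cumsum()
    for pos_end in ends:
        metric = pos_end if design.schedule_mode is ScheduleMode.BY_TOTAL else int(
            cum_pos[pos_end - 1]
        )
        if metric >= point:
            n_pos = int(cum_pos[pos_end - 1])
            return StageCut(
                n_pos=n_pos,
                n_neg=int(pos_end - n_pos),
                n_total=int(pos_end),
                position=int(pos_end),
            )
    return None


def _required_positives(design: DTADesign) -> int:
    if design.schedule_mode is ScheduleMode.BY_POSITIVES:
        return design.target
    return _round_half_up(design.target * _prev_fraction(design.prevalence))


def expected_total_participants(design: DTADesign, prevalence: Optional[float] = None) -> int:
    """Total recruitment needed to reach the positives requirement."""
    prev = _prev_fraction(prevalence if prevalence is not None else design.prevalence)
    if design.schedule_mode is ScheduleMode.BY_TOTAL:
        return design.target
    return math.ceil(design.target / prev)


def reestimate_target(design: DTADesign, observed_prevalence: float) -> DTADesign:
    """Re-anchor the design to a prevalence observed at an interim look.

    The originally required number of disease-positive cases is preserved.
    For ``BY_TOTAL`` designs the participant target becomes
    ``ceil(required_positives / observed_prevalence)``; for ``BY_POSITIVES``
    designs the positives target is already the requirement and only the
    prevalence (hence the projected negatives anchor) changes.  Boundaries
    downstream re-anchor through the rebuilt endpoint plans.
    """
    if not 0 < observed_prevalence < 1:
        raise DesignError(
            f"observed prevalence must be in (0, 1), got {observed_prevalence}"
        )
    required_pos = _required_positives(design)
    if design.schedule_mode is ScheduleMode.BY_TOTAL:
        new_target = math.ceil(
            Fraction(required_pos) / _prev_fraction(observed_prevalence)
        )
    else:
        new_target = design.target
    return make_design(
        prevalence=observed_prevalence,
        schedule_mode=design.schedule_mode,
        schedule_points=design.schedule_points,
        target=new_target,
        sens_p0=design.sens_endpoint.p0,
        spec_p0=design.spec_endpoint.p0,
        alpha=design.sens_endpoint.alpha,
        futility_rule=design.futility_rule,
        sens_efficacy=design.sens_endpoint.efficacy,
        spec_efficacy=design.spec_endpoint.efficacy,
    )


# ---------------------------------------------------------------------------
# Serialization

_SCHEMA_KEYS = {
    "prevalence",
    "schedule",
    "interim_points",
    "target",
    "alpha",
    "sensitivity_p0",
    "specificity_p0",
    "futility_rule",
    "sensitivity_efficacy",
    "specificity_efficacy",
}


def design_to_dict(design: DTADesign) -> dict:
    doc: dict = {
        "prevalence": design.prevalence,
        "schedule": design.schedule_mode.value,
        "interim_points": list(design.schedule_points),
        "target": design.target,
        "alpha": design.sens_endpoint.alpha,
        "sensitivity_p0": design.sens_endpoint.p0,
        "specificity_p0": design.spec_endpoint.p0,
        "futility_rule": design.futility_rule.value,
    }
    for key, ep in (
        ("sensitivity_efficacy", design.sens_endpoint),
        ("specificity_efficacy", design.spec_endpoint),
    ):
        if ep.efficacy is not None:
            doc[key] = {"p_a": ep.efficacy.p_a, "beta": ep.efficacy.beta}
    return doc


def _require(doc: dict, key: str, kind, check=None, message: str = "") -> object:
    if key not in doc:
        raise ConfigError(f"design config: missing required field '{key}'")
    value = doc[key]
    if kind is float and isinstance(value, int) and not isinstance(value, bool):
        value = float(value)
    if not isinstance(value, kind) or isinstance(value, bool):
        raise ConfigError(
            f"design config: field '{key}' must be {kind.__name__}, got {value!r}"
        )
    if check is not None and not check(value):
        raise ConfigError(f"design config: field '{key}' {message}, got {value!r}")
    return value


def _efficacy_from(doc: dict, key: str) -> Optional[EfficacySpec]:
    sub = doc.get(key)
    if sub is None:
        return None
    if not isinstance(sub, dict) or "p_a" not in sub:
        raise ConfigError(f"design config: '{key}' must be a mapping with 'p_a'")
    return EfficacySpec(p_a=float(sub["p_a"]), beta=float(sub.get("beta", 0.05)))


def design_from_dict(doc: dict) -> DTADesign:
    """Validate a plain design document (parsed YAML/JSON) into a design."""
    if not isinstance(doc, dict):
        raise ConfigError("design config: document must be a mapping")
    unknown = set(doc) - _SCHEMA_KEYS
    if unknown:
        raise ConfigError(
            f"design config: unknown field(s) {sorted(unknown)}; "
            f"expected a subset of {sorted(_SCHEMA_KEYS)}"
        )
    prevalence = _require(doc, "prevalence", float, lambda v: 0 < v < 1, "must be in (0, 1)")
    schedule = _require(
        doc,
        "schedule",
        str,
        lambda v: v in {m.value for m in ScheduleMode},
        "must be 'by_total' or 'by_positives'",
    )
    points = _require(doc, "interim_points", list)
    if not all(isinstance(p, int) and not isinstance(p, bool) for p in points):
        raise ConfigError("design config: 'interim_points' must be a list of integers")
    target = _require(doc, "target", int, lambda v: v >= 1, "must be >= 1")
    sens_p0 = _require(doc, "sensitivity_p0", float, lambda v: 0 < v < 1, "must be in (0, 1)")
    spec_p0 = _require(doc, "specificity_p0", float, lambda v: 0 < v < 1, "must be in (0, 1)")
    alpha = float(doc.get("alpha", 0.05))
    rule = doc.get("futility_rule", FutilityRule.EITHER.value)
    if rule not in {r.value for r in FutilityRule}:
        raise ConfigError("design config: 'futility_rule' must be 'either' or 'both'")
    try:
        return make_design(
            prevalence=prevalence,
            schedule_mode=schedule,
            schedule_points=points,
            target=target,
            sens_p0=sens_p0,
            spec_p0=spec_p0,
            alpha=alpha,
            futility_rule=rule,
            sens_efficacy=_efficacy_from(doc, "sensitivity_efficacy"),
            spec_efficacy=_efficacy_from(doc, "specificity_efficacy"),
        )
    except ConfigError:
        raise
    except DesignError as exc:
        raise ConfigError(f"design config: {exc}") from exc


def load_design(path: Union[str, Path]) -> DTADesign:
    """Load a design from a YAML (or JSON) document."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"design config: cannot parse {path}: {exc}") from exc
    return design_from_dict(doc)


def save_design(design: DTADesign, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(design_to_dict(design), sort_keys=False))
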