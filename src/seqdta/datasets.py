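"""Worked-example designs and fixture cohorts.

Two kinds of fixtures are provided, both generated programmatically:

* ``example_cohort(1)`` / ``example_cohort(2)`` -- synthetic 200-participant
  cohorts with the marginal structure of a DTA study whose true sensitivity
  is 65%, specificity 85% and prevalence 35%.  They are reconstructed
  deterministically from per-stage checkpoint counts (total participants,
  disease-positives, true positives and true negatives at every analysis
  cut of both schedules), which is everything interim decisions and
  boundaries depend on; the draw-by-draw order within a segment is a fixed
  convention, not a random realisation.

* ``raptor_cohort("bd_veritor" | "sd_biosensor")`` -- synthetic
  reconstructions of the accrual of two point-of-care SARS-CoV-2 antigen
  tests evaluated against a PCR reference in a platform study, with interim
  analyses as soon as possible after 50, 100 and 150 COVID-19 cases (data
  arrived in daily batches, so the analyses overshoot the milestones: 52/53
  cases at the first look, 103 at the second).  Positive-group counts follow
  the published interim sensitivities; the negative-group sizes are
  synthetic choices consistent with the published specificity estimates and
  boundaries.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .design import DTADesign, FutilityRule, ScheduleMode, make_design

__all__ = [
    "MHRA_PROFILES",
    "example_cohort",
    "raptor_cohort",
    "raptor_design",
    "simulated_design",
]

#: MHRA target product profiles for SARS-CoV-2 point-of-care tests:
#: (sensitivity p0, specificity p0).
MHRA_PROFILES: dict[str, tuple[float, float]] = {
    "desirable": (0.97, 0.99),
    "acceptable": (0.80, 0.95),
}

# Cumulative checkpoints (n_total, positives, TP, TN) at every analysis cut
# used by either schedule, plus a closing checkpoint at full recruitment.
_EXAMPLE_CHECKPOINTS: dict[int, list[tuple[int, int, int, int]]] = {
    1: [
        (25, 8, 6, 13),
        (46, 15, 10, 25),
        (63, 25, 15, 32),
        (75, 29, 18, 38),
        (128, 50, 28, 64),
        (150, 58, 34, 77),
        (200, 70, 41, 108),
    ],
    2: [
        (23, 15, 11, 7),
        (25, 16, 12, 8),
        (41, 25, 18, 14),
        (75, 44, 32, 26),
        (94, 50, 35, 36),
        (150, 72, 48, 64),
        (200, 92, 61, 89),
    ],
}

# Per-device daily checkpoints (n_total, positives, TP, TN); one batch per
# interim milestone.  Negative-group sizes are synthetic (see module
# docstring).
_RAPTOR_CHECKPOINTS: dict[str, list[tuple[int, int, int, int]]] = {
    "bd_veritor": [
        (167, 52, 38, 113),
        (273, 103, 79, 168),
        (380, 150, 118, 227),
    ],
    "sd_biosensor": [
        (137, 53, 47, 82),
        (273, 103, 89, 167),
        (412, 150, 124, 258),
    ],
}


def _segment_records(
    checkpoints: Iterable[tuple[int, int, int, int]]
) -> tuple[list[int], list[int]]:
    """Expand cumulative checkpoints into per-record reference/index lists.

    Within each segment negatives are emitted first (true negatives, then
    false positives) and positives last (true positives, then false
    negatives), so cumulative positive counts first reach a checkpoint value
    exactly at the checkpoint position.
    """
    reference: list[int] = []
    index: list[int] = []
    prev = (0, 0, 0, 0)
    for cp in checkpoints:
        n, pos, tp, tn = cp
        d_n = n - prev[0]
        d_pos = pos - prev[1]
        d_tp = tp - prev[2]
        d_tn = tn - prev[3]
        d_neg = d_n - d_pos
        d_fp = d_neg - d_tn
        d_fn = d_pos - d_tp
        if min(d_pos, d_tp, d_tn, d_fp, d_fn) < 0:
            raise ValueError(f"inconsistent checkpoint {cp} after {prev}")
        reference += [0] * d_neg + [1] * d_pos
        index += [0] * d_tn + [1] * d_fp + [1] * d_tp + [0] * d_fn
        prev = cp
    return reference, index


def _to_frame(reference: list[int], index: list[int]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "order": np.arange(1, len(reference) + 1),
            "reference": reference,
            "index": index,
        }
    )


def example_cohort(which: int) -> pd.DataFrame:
    """Deterministic synthetic example cohort (1 or 2), 200 participants."""
    if which not in _EXAMPLE_CHECKPOINTS:
        raise ValueError(f"example cohort must be 1 or 2, got {which}")
    return _to_frame(*_segment_records(_EXAMPLE_CHECKPOINTS[which]))


def raptor_cohort(device: str) -> pd.DataFrame:
    """Synthetic reconstruction of one device's accrual, with daily batches.

    The returned frame carries a ``day`` column marking batch availability:
    each interim milestone is crossed mid-batch, reproducing the overshoot
    of the published interim looks.
    """
    if device not in _RAPTOR_CHECKPOINTS:
        raise ValueError(
            f"device must be one of {sorted(_RAPTOR_CHECKPOINTS)}, got {device!r}"
        )
    checkpoints = _RAPTOR_CHECKPOINTS[device]
    reference, index = _segment_records(checkpoints)
    frame = _to_frame(reference, index)
    day = np.empty(len(frame), dtype=int)
    start = 0
    for d, cp in enumerate(checkpoints, start=1):
        day[start : cp[0]] = d
        start = cp[0]
    frame["day"] = day
    return frame


def simulated_design(schedule_mode: str | ScheduleMode) -> DTADesign:
    """The worked-example monitoring plan for the simulated cohorts.

    200 planned participants at an assumed prevalence of 35%, minimum
    acceptable sensitivity 75% and specificity 90%, one-sided alpha 0.05 per
    endpoint.  ``BY_TOTAL`` schedules interims after 25/75/150 participants;
    ``BY_POSITIVES`` after 15/25/50 disease-positive cases (final anchor 70
    positives / 130 negatives either way).
    """
    mode = ScheduleMode(schedule_mode)
    if mode is ScheduleMode.BY_TOTAL:
        points, target = (25, 75, 150), 200
    else:
        points, target = (15, 25, 50), 70
    return make_design(
        prevalence=0.35,
        schedule_mode=mode,
        schedule_points=points,
        target=target,
        sens_p0=0.75,
        spec_p0=0.90,
        alpha=0.05,
        futility_rule=FutilityRule.EITHER,
    )


def raptor_design(profile: str) -> DTADesign:
    """The case-study monitoring plan under an MHRA target product profile.

    Interim analyses after 50 and 100 COVID-19 cases with a final target of
    150 cases, assumed prevalence 30% (so the specificity endpoint anchors
    to 350 projected negatives).
    """
    if profile not in MHRA_PROFILES:
        raise ValueError(f"profile must be one of {sorted(MHRA_PROFILES)}, got {profile!r}")
    sens_p0, spec_p0 = MHRA_PROFILES[profile]
    return make_design(
        prevalence=0.30,
        schedule_mode=ScheduleMode.BY_POSITIVES,
        schedule_points=(50, 100),
        target=150,
        sens_p0=sens_p0,
        spec_p0=spec_p0,
        alpha=0.05,
        futility_rule=FutilityRule.EITHER,
    )
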