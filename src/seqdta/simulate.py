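"""Synthetic DTA cohorts and Monte-Carlo operating characteristics.

A cohort scenario draws, for each participant in recruitment order,

    reference ~ Bernoulli(prevalence)
    index | reference = 1 ~ Bernoulli(sensitivity)
    index | reference = 0 ~ Bernoulli(1 - specificity)

so the simulated data have exactly the structure the monitoring engine
consumes.  :func:`simulate_oc` replays the full monitoring schedule over
many independent cohorts to estimate stagewise stopping frequencies, the
overall futility rate and the expected terminal sample size -- the
empirical counterparts of the exact recursion in :mod:`seqdta.boundaries`.

All randomness flows from a single root seed through one numpy Generator
consumed in a fixed chunked order, so results are bit-reproducible for a
given package version.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .boundaries import DesignError, EndpointDesign
from .design import DTADesign, FutilityRule, ScheduleMode, expected_total_participants

__all__ = ["CohortScenario", "OCSummary", "default_cohort_size", "simulate_cohort", "simulate_oc"]


@dataclass(frozen=True)
class CohortScenario:
    """Generating truth for a synthetic single-gate DTA cohort."""

    prevalence: float
    sensitivity: float
    specificity: float
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prevalence", "sensitivity", "specificity"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise DesignError(f"{name} must be in [0, 1], got {value}")
        if self.n < 0:
            raise DesignError(f"cohort size must be non-negative, got {self.n}")


@dataclass(frozen=True)
class OCSummary:
    """Monte-Carlo operating characteristics of a design under a scenario.

    Stage vectors have one entry per analysis (interims then final); the
    frequencies plus ``no_stop`` sum to one.  Replicates whose accrual never
    reaches a milestone are counted as not stopping there.
    """

    stage_futility: tuple[float, ...]
    stage_efficacy: tuple[float, ...]
    no_stop: float
    futility_frequency: float
    efficacy_frequency: float
    mean_terminal_n: float
    replicates: int
    futility_se: float
    mean_terminal_n_se: float

    @property
    def stage_futility_se(self) -> tuple[float, ...]:
        r = self.replicates
        return tuple(math.sqrt(f * (1 - f) / r) for f in self.stage_futility)


def simulate_cohort(scenario: CohortScenario) -> pd.DataFrame:
    """Generate one cohort as an ordered participant table."""
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n
    ref = rng.random(n) < scenario.prevalence
    pos_draw = rng.random(n) < scenario.sensitivity
    neg_draw = rng.random(n) < (1.0 - scenario.specificity)
    index = np.where(ref, pos_draw, neg_draw)
    return pd.DataFrame(
        {
            "order": np.arange(1, n + 1),
            "reference": ref.astype(int),
            "index": index.astype(int),
        }
    )


def default_cohort_size(design: DTADesign) -> int:
    """A cohort size that almost surely reaches the final milestone.

    ``BY_TOTAL`` schedules need exactly the target; ``BY_POSITIVES``
    schedules accrue positives at the prevalence rate, so the expected
    recruitment is inflated by five prevalence standard deviations.
    """
    if design.schedule_mode is ScheduleMode.BY_TOTAL:
        return design.target
    expected = expected_total_participants(design)
    margin = 5.0 * math.sqrt(
        expected * design.prevalence * (1.0 - design.prevalence)
    ) / design.prevalence
    return int(math.ceil(expected + margin))


def _stage_counts(
    endpoint: EndpointDesign, n: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised futility (and efficacy) counts at observed sizes ``n``."""
    p_t = endpoint.p_t
    dev = stats.norm.ppf(1.0 - endpoint.alpha) * math.sqrt(
        endpoint.anchor_size * p_t * (1.0 - p_t)
    )
    r = np.floor(n * p_t + 0.5 + dev).astype(np.int64) + 1
    r = np.maximum(r, 0)
    if endpoint.efficacy is None:
        a = np.full_like(r, -1)
    else:
        p_a, beta = endpoint.efficacy.p_a, endpoint.efficacy.beta
        dev_a = stats.norm.ppf(1.0 - beta) * math.sqrt(
            endpoint.anchor_size * p_a * (1.0 - p_a)
        )
        a = np.ceil(n * p_a - 0.5 - dev_a).astype(np.int64) - 1
        a = np.minimum(a, r - 1)
        a = np.where(n >= endpoint.anchor_size, r - 1, a)
    return r, a


def simulate_oc(
    design: DTADesign,
    scenario: CohortScenario,
    replicates: int,
    seed: Optional[int] = None,
) -> OCSummary:
    """Estimate operating characteristics by replaying the monitor.

    Equivalent to running :func:`seqdta.interim.monitor` on ``replicates``
    independent cohorts drawn from ``scenario`` (vectorised across
    replicates for speed; per-record batching is not simulated, so every
    milestone is evaluated at its exact crossing).
    """
    if replicates < 1:
        raise DesignError(f"replicates must be >= 1, got {replicates}")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n = scenario.n
    points = design.schedule_points + (design.target,)
    n_stages = len(points)
    stage_fut = np.zeros(n_stages, dtype=np.int64)
    stage_eff = np.zeros(n_stages, dtype=np.int64)
    terminal_sum = 0.0
    terminal_sumsq = 0.0

    chunk = max(1, min(replicates, max(1, 4_000_000 // max(n, 1))))
    done = 0
    while done < replicates:
        c = min(chunk, replicates - done)
        ref = rng.random((c, n)) < scenario.prevalence
        fn_draw = rng.random((c, n)) >= scenario.sensitivity
        fp_draw = rng.random((c, n)) >= scenario.specificity
        cum_pos = np.cumsum(ref, axis=1)
        cum_fn = np.cumsum(ref & fn_draw, axis=1)
        cum_fp = np.cumsum(~ref & fp_draw, axis=1)
        totals = np.arange(1, n + 1)

        active = np.ones(c, dtype=bool)
        terminal = np.full(c, float(n))
        for g, point in enumerate(points):
            if design.schedule_mode is ScheduleMode.BY_TOTAL:
                if point > n:
                    break
                cut = np.full(c, point - 1)
                reached = active.copy()
            else:
                hit = cum_pos >= point
                reached = active & hit[:, -1]
                cut = np.argmax(hit, axis=1)
            if not reached.any():
                continue
            rows = np.nonzero(reached)[0]
            col = cut[rows]
            n_pos = cum_pos[rows, col]
            n_neg = totals[col] - n_pos
            fn = cum_fn[rows, col]
            fp = cum_fp[rows, col]

            stop_f = np.zeros(len(rows), dtype=bool)
            stop_e = np.ones(len(rows), dtype=bool)
            any_evaluable = np.zeros(len(rows), dtype=bool)
            fut_flags = []
            for group_n, failures, endpoint in (
                (n_pos, fn, design.sens_endpoint),
                (n_neg, fp, design.spec_endpoint),
            ):
                evaluable = group_n > 0
                r, a = _stage_counts(endpoint, np.maximum(group_n, 1))
                futile = evaluable & (r <= group_n) & (failures >= r)
                efficacious = evaluable & (a >= 0) & (failures <= a)
                fut_flags.append((futile, evaluable))
                stop_e &= np.where(evaluable, efficacious, True)
                any_evaluable |= evaluable
            if design.futility_rule is FutilityRule.EITHER:
                stop_f = fut_flags[0][0] | fut_flags[1][0]
            else:
                stop_f = (
                    np.where(fut_flags[0][1], fut_flags[0][0], True)
                    & np.where(fut_flags[1][1], fut_flags[1][0], True)
                    & any_evaluable
                )
            stop_e &= any_evaluable & ~stop_f
            stage_fut[g] += int(stop_f.sum())
            stage_eff[g] += int(stop_e.sum())
            stopped = stop_f | stop_e
            stop_rows = rows[stopped]
            terminal[stop_rows] = col[stopped] + 1.0
            active[stop_rows] = False
            if g == n_stages - 1:
                # Final analysis reached without stopping: recruitment ends.
                terminal[rows[~stopped]] = col[~stopped] + 1.0
        terminal_sum += float(terminal.sum())
        terminal_sumsq += float((terminal**2).sum())
        done += c

    r_total = replicates
    fut_freq = float(stage_fut.sum()) / r_total
    eff_freq = float(stage_eff.sum()) / r_total
    mean_n = terminal_sum / r_total
    var_n = max(terminal_sumsq / r_total - mean_n**2, 0.0)
    return OCSummary(
        stage_futility=tuple(stage_fut / r_total),
        stage_efficacy=tuple(stage_eff / r_total),
        no_stop=1.0 - fut_freq - eff_freq,
        futility_frequency=fut_freq,
        efficacy_frequency=eff_freq,
        mean_terminal_n=mean_n,
        replicates=r_total,
        futility_se=math.sqrt(fut_freq * (1.0 - fut_freq) / r_total),
        mean_terminal_n_se=math.sqrt(var_n / r_total),
    )
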