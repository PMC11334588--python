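"""Exact group sequential stopping boundaries for a single error proportion.

Diagnostic accuracy studies monitor two co-primary proportions, sensitivity
and specificity.  Group sequential methods for a single binomial proportion
assume the monitored proportion is below 0.5, so the endpoints are monitored
through their complements: the false-negative rate (FNR = 1 - sensitivity)
and the false-positive rate (FPR = 1 - specificity).  The hypotheses for one
endpoint are

    H0: p <= p_t        (the test is acceptable)
    H1: p >  p_t        (the test is futile)

where ``p`` is the true error rate and ``p_t = 1 - p0`` is the threshold
error proportion corresponding to the minimally acceptable accuracy ``p0``.
Rejecting H0 at an interim analysis stops the study for futility.

The futility boundary at a stage with cumulative endpoint-group size ``n_g``
is the smallest failure count that rejects H0,

    r_g = floor(n_g * p_t + 0.5 + z_{1-alpha} * sqrt(n_G * p_t * (1 - p_t))) + 1,

anchored to the planned final group size ``n_G``: the normal-deviate term is
evaluated at the final analysis, so interim boundaries demand stronger
evidence than the final one.  When ``r_g > n_g`` stopping is impossible at
that stage (rendered as a dash on the accuracy scale).

Exact operating characteristics (stagewise stopping probabilities, type I
error, expected sample size) are computed by forward recursion over the
failure-count process, not by normal approximation.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

__all__ = [
    "DASH",
    "UNATTAINABLE",
    "BoundarySet",
    "DesignError",
    "EfficacySpec",
    "EndpointDesign",
    "EndpointLabel",
    "MethodAssumptionWarning",
    "StagewiseProbabilities",
    "boundary_set",
    "efficacy_boundary_count",
    "exact_type_I_error",
    "expected_sample_size",
    "futility_boundary_count",
    "stagewise_probabilities",
]

MAX_RECOMMENDED_ANALYSES = 5


class DesignError(ValueError):
    """Raised when design parameters are invalid."""


class MethodAssumptionWarning(UserWarning):
    """Emitted when a design violates a soft assumption of the method."""


class _Marker(enum.Enum):
    """Sentinels for impossible stopping (count scale / accuracy scale)."""

    UNATTAINABLE = "unattainable"
    DASH = "-"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: Failure-count boundary larger than the group size: stopping impossible.
UNATTAINABLE = _Marker.UNATTAINABLE
#: Accuracy-scale boundary below 0%, printed as a dash in reports.
DASH = _Marker.DASH

Count = Union[int, _Marker]
Boundary = Union[Fraction, _Marker]


class EndpointLabel(str, enum.Enum):
    """Which error rate an endpoint monitors."""

    FNR = "FNR"  # 1 - sensitivity, over disease-positive participants
    FPR = "FPR"  # 1 - specificity, over disease-negative participants


@dataclass(frozen=True)
class EfficacySpec:
    """Parameters of an optional acceptance (efficacy) boundary.

    ``p_a`` is an error rate low enough to accept the test early and
    ``beta`` the tolerated probability of failing to accept when the true
    error rate is ``p_a``.  Early acceptance is rarely appropriate in
    diagnostic accuracy studies and is disabled by default.
    """

    p_a: float
    beta: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.p_a < 1:
            raise DesignError(f"efficacy p_a must be in [0, 1), got {self.p_a}")
        if not 0 < self.beta < 1:
            raise DesignError(f"efficacy beta must be in (0, 1), got {self.beta}")


@dataclass(frozen=True)
class EndpointDesign:
    """Monitoring plan for a single error-rate endpoint (FNR or FPR).

    Parameters
    ----------
    label
        Which error rate is monitored.
    p0
        Minimally acceptable accuracy (sensitivity or specificity) on the
        success scale; the monitored threshold error rate is ``p_t = 1 - p0``.
    stage_sizes
        Cumulative endpoint-group sizes ``n_1 < ... < n_{G-1}`` at each
        planned interim analysis.  May be empty (no interims).
    anchor_size
        Planned final endpoint-group size ``n_G`` to which all boundaries
        are anchored.  Observed interim sizes may overshoot it.
    alpha
        One-sided type I error rate for this endpoint.
    efficacy
        Optional acceptance-boundary parameters; ``None`` disables early
        stopping for efficacy.
    """

    label: EndpointLabel
    p0: float
    stage_sizes: tuple[int, ...]
    anchor_size: int
    alpha: float = 0.05
    efficacy: Optional[EfficacySpec] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", EndpointLabel(self.label))
        object.__setattr__(self, "stage_sizes", tuple(int(n) for n in self.stage_sizes))
        if not 0 < self.p0 < 1:
            raise DesignError(f"p0 must be in (0, 1), got {self.p0}")
        if not 0 < self.alpha < 1:
            raise DesignError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.anchor_size < 1:
            raise DesignError(f"anchor_size must be >= 1, got {self.anchor_size}")
        if any(n < 1 for n in self.stage_sizes):
            raise DesignError("stage sizes must be positive")
        if any(b <= a for a, b in zip(self.stage_sizes, self.stage_sizes[1:])):
            raise DesignError(f"stage sizes must be strictly increasing: {self.stage_sizes}")
        if self.efficacy is not None and self.efficacy.p_a >= self.p_t:
            raise DesignError(
                f"efficacy p_a ({self.efficacy.p_a}) must be below p_t ({self.p_t})"
            )
        if self.p_t >= 0.5:
            warnings.warn(
                f"threshold error proportion p_t = {self.p_t:.3f} is not below 0.5; "
                "the exact group sequential method assumes p_t < 0.5",
                MethodAssumptionWarning,
                stacklevel=2,
            )
        n_analyses = len(self.stage_sizes) + 1
        if n_analyses > MAX_RECOMMENDED_ANALYSES:
            warnings.warn(
                f"{n_analyses} analyses planned; more than {MAX_RECOMMENDED_ANALYSES} "
                "is not recommended for the exact group sequential method",
                MethodAssumptionWarning,
                stacklevel=2,
            )

    @property
    def p_t(self) -> float:
        """Threshold error proportion, ``1 - p0``."""
        return 1.0 - self.p0

    @property
    def n_analyses(self) -> int:
        """Number of analyses, interims plus final."""
        return len(self.stage_sizes) + 1

    def all_stage_sizes(self) -> tuple[int, ...]:
        """Planned cumulative group sizes including the final anchor."""
        return self.stage_sizes + (self.anchor_size,)


@dataclass(frozen=True)
class BoundarySet:
    """Stagewise stopping boundaries on the count and accuracy scales.

    ``futility_counts[g]`` is the smallest failure count that stops for
    futility at stage ``g`` (or :data:`UNATTAINABLE`).  The accuracy-scale
    boundary ``1 - r_g / n_g`` is stored as an exact :class:`Fraction`, or
    :data:`DASH` when it would fall below zero.
    """

    stage_sizes: tuple[int, ...]
    futility_counts: tuple[Count, ...]
    accuracy_boundaries: tuple[Boundary, ...]
    efficacy_counts: Optional[tuple[Count, ...]] = None

    def __post_init__(self) -> None:
        k = len(self.stage_sizes)
        if not (len(self.futility_counts) == len(self.accuracy_boundaries) == k):
            raise DesignError("boundary vectors must have one entry per stage")
        if self.efficacy_counts is not None and len(self.efficacy_counts) != k:
            raise DesignError("efficacy_counts must have one entry per stage")
        if any(b <= a for a, b in zip(self.stage_sizes, self.stage_sizes[1:])):
            raise DesignError("stage sizes must be strictly increasing")

    @property
    def n_stages(self) -> int:
        return len(self.stage_sizes)


@dataclass(frozen=True)
class StagewiseProbabilities:
    """Exact stagewise stopping probabilities at a true error rate ``p``.

    ``futility[g]`` / ``efficacy[g]`` are the probabilities of first stopping
    at stage ``g`` for the corresponding reason; ``no_stop`` is the
    probability of completing the final analysis without crossing any
    boundary.  Entries sum to one.
    """

    futility: tuple[float, ...]
    efficacy: tuple[float, ...]
    no_stop: float
    p: float

    @property
    def total_futility(self) -> float:
        return float(sum(self.futility))

    @property
    def total_efficacy(self) -> float:
        return float(sum(self.efficacy))


def _deviate(design: EndpointDesign, rate: float, quantile: float) -> float:
    return stats.norm.ppf(quantile) * math.sqrt(
        design.anchor_size * rate * (1.0 - rate)
    )


def futility_boundary_count(n_g: int, design: EndpointDesign) -> Count:
    """Smallest failure count rejecting H0 at a stage of size ``n_g``.

    Returns :data:`UNATTAINABLE` when the count exceeds ``n_g``, i.e. no
    possible outcome stops at this stage.
    """
    n_g = int(n_g)
    if n_g < 1:
        raise DesignError(f"stage size must be >= 1, got {n_g}")
    r = math.floor(n_g * design.p_t + 0.5 + _deviate(design, design.p_t, 1.0 - design.alpha)) + 1
    r = max(r, 0)
    return UNATTAINABLE if r > n_g else r


def efficacy_boundary_count(n_g: int, design: EndpointDesign) -> Count:
    """Largest failure count accepting H0 early at a stage of size ``n_g``.

    Mirrors the futility construction with the acceptance error rate
    ``p_a`` and ``z_{1-beta}``, subtracting the deviate term.  At the final
    stage the count is forced to sit just below the futility count so the
    final analysis always terminates with a decision.  Returns
    :data:`UNATTAINABLE` when the count is negative.
    """
    if design.efficacy is None:
        raise DesignError("endpoint design has no efficacy parameters configured")
    n_g = int(n_g)
    if n_g < 1:
        raise DesignError(f"stage size must be >= 1, got {n_g}")
    p_a, beta = design.efficacy.p_a, design.efficacy.beta
    r = futility_boundary_count(n_g, design)
    r_int = n_g + 1 if r is UNATTAINABLE else int(r)
    if n_g >= design.anchor_size:
        a = r_int - 1
    else:
        a = math.ceil(n_g * p_a - 0.5 - _deviate(design, p_a, 1.0 - beta)) - 1
        a = min(a, r_int - 1)
    return UNATTAINABLE if a < 0 else a


def boundary_set(design: EndpointDesign) -> BoundarySet:
    """Compute the full set of stagewise boundaries, final stage included."""
    sizes = design.all_stage_sizes()
    futility: list[Count] = []
    accuracy: list[Boundary] = []
    for n_g in sizes:
        r = futility_boundary_count(n_g, design)
        futility.append(r)
        accuracy.append(DASH if r is UNATTAINABLE else Fraction(n_g - int(r), n_g))
    efficacy: Optional[tuple[Count, ...]] = None
    if design.efficacy is not None:
        efficacy = tuple(efficacy_boundary_count(n_g, design) for n_g in sizes)
    return BoundarySet(
        stage_sizes=sizes,
        futility_counts=tuple(futility),
        accuracy_boundaries=tuple(accuracy),
        efficacy_counts=efficacy,
    )


def _count_or(value: Optional[Count], default: int) -> int:
    if value is None or value is UNATTAINABLE:
        return default
    return int(value)


def stagewise_probabilities(boundaries: BoundarySet, p: float) -> StagewiseProbabilities:
    """Exact stopping probabilities by forward recursion over failure counts.

    The distribution of the cumulative failure count is propagated stage by
    stage: the binomial mass of each incremental group is convolved with the
    surviving mass, the mass at or beyond the futility count (and at or
    below the efficacy count, when enabled) is harvested as the stopping
    probability, and the remainder continues.  Mass surviving the final
    stage is the no-stop probability.
    """
    if not 0.0 <= p <= 1.0:
        raise DesignError(f"p must be in [0, 1], got {p}")
    sizes = boundaries.stage_sizes
    futility_probs: list[float] = []
    efficacy_probs: list[float] = []
    surviving = np.array([1.0])  # mass over cumulative failure counts 0..n_prev
    n_prev = 0
    for g, n_g in enumerate(sizes):
        m = n_g - n_prev
        if m > 0:
            increment = stats.binom.pmf(np.arange(m + 1), m, p)
            surviving = np.convolve(surviving, increment)
        r = _count_or(boundaries.futility_counts[g], n_g + 1)
        a = _count_or(
            boundaries.efficacy_counts[g] if boundaries.efficacy_counts else None, -1
        )
        r = min(r, n_g + 1)
        futility_probs.append(float(surviving[r:].sum()))
        efficacy_probs.append(float(surviving[: a + 1].sum()) if a >= 0 else 0.0)
        surviving = surviving.copy()
        surviving[r:] = 0.0
        if a >= 0:
            surviving[: a + 1] = 0.0
        n_prev = n_g
    return StagewiseProbabilities(
        futility=tuple(futility_probs),
        efficacy=tuple(efficacy_probs),
        no_stop=float(surviving.sum()),
        p=float(p),
    )


def exact_type_I_error(boundaries: BoundarySet, design: EndpointDesign) -> float:
    """Exact probability of (wrongly) stopping for futility at ``p = p_t``.

    The futility-stop probability is non-decreasing in the true error rate,
    so evaluating at the threshold ``p_t`` gives the supremum over H0.
    """
    return stagewise_probabilities(boundaries, design.p_t).total_futility


def expected_sample_size(boundaries: BoundarySet, p: float) -> float:
    """Expected terminal endpoint-group size at a true error rate ``p``."""
    probs = stagewise_probabilities(boundaries, p)
    sizes = boundaries.stage_sizes
    expected = sum(
        n_g * (pf + pe)
        for n_g, pf, pe in zip(sizes, probs.futility, probs.efficacy)
    )
    return float(expected + sizes[-1] * probs.no_stop)
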