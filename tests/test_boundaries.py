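"""Boundary construction and exact operating characteristics."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from seqdta import (
    DASH,
    UNATTAINABLE,
    DesignError,
    EfficacySpec,
    EndpointDesign,
    MethodAssumptionWarning,
    boundary_set,
    efficacy_boundary_count,
    exact_type_I_error,
    expected_sample_size,
    futility_boundary_count,
    stagewise_probabilities,
)

from _enumeration import enumerate_stagewise


@pytest.mark.parametrize(
    "n_g, p0, anchor, expected",
    [
        (29, 0.75, 70, 14),  # second by-total look of the worked example
        (8, 0.75, 70, UNATTAINABLE),  # too few positives to ever stop
        (52, 0.97, 150, 6),  # first case-study look, desirable profile
        (15, 0.75, 70, 11),  # first by-positives look
        (72, 0.75, 70, 25),  # observed overshoot past the planned anchor
    ],
)
def test_futility_count_matches_published_designs(n_g, p0, anchor, expected):
    design = EndpointDesign("FNR", p0, (), anchor)
    assert futility_boundary_count(n_g, design) == expected


def test_futility_count_rejects_invalid_inputs():
    design = EndpointDesign("FNR", 0.75, (), 70)
    with pytest.raises(DesignError):
        futility_boundary_count(0, design)
    with pytest.raises(DesignError):
        EndpointDesign("FNR", 1.2, (), 70)
    with pytest.raises(DesignError):
        EndpointDesign("FNR", 0.75, (), 0)
    with pytest.raises(DesignError):
        EndpointDesign("FNR", 0.75, (10, 5), 70)


def test_assumption_warnings():
    with pytest.warns(MethodAssumptionWarning, match="0.5"):
        EndpointDesign("FNR", 0.4, (), 70)  # p_t = 0.6 violates the assumption
    with pytest.warns(MethodAssumptionWarning, match="analyses"):
        EndpointDesign("FNR", 0.75, (10, 20, 30, 40, 50), 70)


def test_boundary_set_worked_example(sens_endpoint_by_positives):
    bs = boundary_set(sens_endpoint_by_positives)
    assert bs.stage_sizes == (15, 25, 50, 70)
    assert bs.futility_counts == (11, 13, 19, 24)
    assert bs.accuracy_boundaries[0] == Fraction(4, 15)
    # counts non-decreasing, interim accuracy boundaries strictly below p0,
    # final boundary the closest to p0
    counts = [int(c) for c in bs.futility_counts]
    assert counts == sorted(counts)
    gaps = [0.75 - float(b) for b in bs.accuracy_boundaries]
    assert all(g > 0 for g in gaps)
    assert gaps[-1] == min(gaps)


def test_boundary_set_dash_marks_unattainable_stages():
    bs = boundary_set(EndpointDesign("FNR", 0.75, (8, 29, 58), 70))
    assert bs.futility_counts[0] is UNATTAINABLE
    assert bs.accuracy_boundaries[0] is DASH
    assert bs.accuracy_boundaries[1] == Fraction(15, 29)


def test_single_stage_design_reduces_to_one_stage_critical_value():
    design = EndpointDesign("FPR", 0.90, (), 130)
    bs = boundary_set(design)
    assert bs.stage_sizes == (130,)
    assert bs.futility_counts == (futility_boundary_count(130, design),)


class TestEfficacyBoundary:
    def test_requires_configuration(self):
        with pytest.raises(DesignError, match="efficacy"):
            efficacy_boundary_count(10, EndpointDesign("FNR", 0.75, (), 70))

    def test_zero_error_rate_is_never_acceptable_early(self):
        design = EndpointDesign(
            "FNR", 0.75, (10,), 70, efficacy=EfficacySpec(p_a=0.0, beta=0.05)
        )
        assert efficacy_boundary_count(10, design) is UNATTAINABLE

    def test_final_stage_always_terminates(self):
        design = EndpointDesign(
            "FNR", 0.75, (10,), 70, efficacy=EfficacySpec(p_a=0.05, beta=0.05)
        )
        r = futility_boundary_count(70, design)
        assert efficacy_boundary_count(70, design) == int(r) - 1

    def test_acceptance_below_rejection_at_every_stage(self):
        design = EndpointDesign(
            "FNR", 0.7, (10, 20), 30, efficacy=EfficacySpec(p_a=0.05, beta=0.2)
        )
        bs = boundary_set(design)
        for r, a in zip(bs.futility_counts, bs.efficacy_counts):
            if r is not UNATTAINABLE and a is not UNATTAINABLE:
                assert int(a) < int(r)


def test_single_stage_probability_is_binomial_tail():
    design = EndpointDesign("FNR", 0.8, (), 20)
    bs = boundary_set(design)
    r = int(bs.futility_counts[0])
    probs = stagewise_probabilities(bs, 0.3)
    expected = stats.binom.sf(r - 1, 20, 0.3)
    assert probs.futility[0] == pytest.approx(expected, abs=1e-12)
    assert probs.no_stop == pytest.approx(1 - expected, abs=1e-12)


@pytest.mark.parametrize("p", [0.0, 0.1, 0.25, 0.5, 0.9, 1.0])
def test_probabilities_conserve_mass(sens_endpoint_by_positives, p):
    bs = boundary_set(sens_endpoint_by_positives)
    probs = stagewise_probabilities(bs, p)
    total = sum(probs.futility) + sum(probs.efficacy) + probs.no_stop
    assert total == pytest.approx(1.0, abs=1e-12)
    assert all(0 <= q <= 1 for q in probs.futility + probs.efficacy)


def test_futility_probability_monotone_in_p(sens_endpoint_by_positives):
    bs = boundary_set(sens_endpoint_by_positives)
    grid = [stagewise_probabilities(bs, p).total_futility for p in np.linspace(0, 1, 11)]
    assert all(b >= a for a, b in zip(grid, grid[1:]))
    p_t = sens_endpoint_by_positives.p_t
    assert (
        stagewise_probabilities(bs, p_t / 2).total_futility
        < stagewise_probabilities(bs, p_t).total_futility
    )


def test_exact_type_one_error_of_worked_example(sens_endpoint_by_positives):
    bs = boundary_set(sens_endpoint_by_positives)
    alpha = exact_type_I_error(bs, sens_endpoint_by_positives)
    # Fleming-type anchored boundaries are approximate: the exact level sits
    # near, not exactly at, the nominal one-sided 0.05.
    assert 0.0 < alpha < 0.10


def test_exact_type_one_error_reduces_to_final_tail_when_interims_unattainable():
    design = EndpointDesign("FNR", 0.75, (8,), 70)
    bs = boundary_set(design)
    assert bs.futility_counts[0] is UNATTAINABLE
    r = int(bs.futility_counts[-1])
    assert exact_type_I_error(bs, design) == pytest.approx(
        stats.binom.sf(r - 1, 70, 0.25), abs=1e-12
    )


class TestExpectedSampleSize:
    def test_all_unattainable_returns_anchor(self):
        # alpha so strict no failure count can reject, even at the final look
        design = EndpointDesign("FNR", 0.55, (2,), 4, alpha=0.001)
        bs = boundary_set(design)
        assert all(c is UNATTAINABLE for c in bs.futility_counts)
        assert expected_sample_size(bs, 0.3) == pytest.approx(4.0, abs=1e-12)

    def test_certain_failure_stops_at_first_attainable_stage(self):
        design = EndpointDesign("FNR", 0.75, (15, 25, 50), 70)
        bs = boundary_set(design)
        assert int(bs.futility_counts[0]) <= 15
        assert expected_sample_size(bs, 1.0) == pytest.approx(15.0, abs=1e-12)

    def test_bounded_by_first_and_final_stage(self, sens_endpoint_by_positives):
        bs = boundary_set(sens_endpoint_by_positives)
        for p in (0.1, 0.25, 0.4):
            assert 15.0 <= expected_sample_size(bs, p) <= 70.0


def _tiny_boundary_sets():
    """Small designs (n_G <= 12, at most 3 analyses) for oracle comparison."""
    designs = [
        EndpointDesign("FNR", 0.7, (3, 6), 12),
        EndpointDesign("FNR", 0.7, (3, 6), 12, alpha=0.2),
        EndpointDesign("FNR", 0.8, (4, 8), 10),
        EndpointDesign("FPR", 0.9, (2, 5), 9),
        EndpointDesign("FNR", 0.75, (5,), 12),
        EndpointDesign("FNR", 0.6, (), 8),
        EndpointDesign(
            "FNR", 0.7, (4, 8), 12, alpha=0.2, efficacy=EfficacySpec(p_a=0.05, beta=0.2)
        ),
        EndpointDesign(
            "FNR", 0.7, (5, 10), 12, efficacy=EfficacySpec(p_a=0.02, beta=0.1)
        ),
    ]
    return [boundary_set(d) for d in designs]


@pytest.mark.parametrize("p", [0.1, 0.3, 0.5])
def test_recursion_matches_path_enumeration(p):
    for bs in _tiny_boundary_sets():
        fut, eff, no_stop, esize = enumerate_stagewise(bs, p)
        probs = stagewise_probabilities(bs, p)
        assert np.allclose(probs.futility, fut, atol=1e-10)
        assert np.allclose(probs.efficacy, eff, atol=1e-10)
        assert probs.no_stop == pytest.approx(no_stop, abs=1e-10)
        assert expected_sample_size(bs, p) == pytest.approx(esize, abs=1e-9)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    p0=st.floats(0.51, 0.99),
    alpha=st.floats(0.01, 0.3),
    sizes=st.lists(st.integers(1, 60), min_size=1, max_size=4, unique=True),
    p=st.floats(0.0, 1.0),
)
def test_conservation_property(p0, alpha, sizes, p):
    """Stagewise probabilities always form a distribution over outcomes."""
    sizes = sorted(sizes)
    design = EndpointDesign("FNR", p0, tuple(sizes[:-1]), sizes[-1] + 5, alpha=alpha)
    probs = stagewise_probabilities(boundary_set(design), p)
    total = sum(probs.futility) + sum(probs.efficacy) + probs.no_stop
    assert math.isclose(total, 1.0, abs_tol=1e-12)
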