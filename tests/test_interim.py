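"""Interim decision engine: tabulation, decisions, monitoring."""

from fractions import Fraction

import pandas as pd
import pytest

from seqdta import (
    AccuracyTable,
    DataError,
    Decision,
    evaluate_interim,
    make_design,
    monitor,
    read_participants,
    tabulate,
)
from seqdta.boundaries import futility_boundary_count


def _records(reference, index):
    return pd.DataFrame(
        {
            "order": range(1, len(reference) + 1),
            "reference": list(reference),
            "index": list(index),
        }
    )


class TestTabulate:
    def test_hand_counted_table(self):
        recs = _records([1, 1, 0], [1, 0, 0])
        table = tabulate(recs, 3)
        assert (table.tp, table.fn, table.tn, table.fp) == (1, 1, 1, 0)

    def test_empty_prefix(self, cohort1):
        table = tabulate(cohort1, 0)
        assert (table.tp, table.fn, table.tn, table.fp) == (0, 0, 0, 0)
        assert table.sensitivity is None and table.specificity is None

    def test_worked_example_first_look(self, cohort1):
        table = tabulate(cohort1, 46)
        assert table.n_pos == 15 and table.n_neg == 31
        assert table.sensitivity == Fraction(10, 15)
        assert table.specificity == Fraction(25, 31)

    def test_upto_beyond_data_rejected(self, cohort1):
        with pytest.raises(DataError):
            tabulate(cohort1, len(cohort1) + 1)


class TestEvaluateInterim:
    def test_estimate_equal_to_boundary_stops(self, design_by_positives):
        # sensitivity failures exactly at the stopping count
        r = futility_boundary_count(15, design_by_positives.sens_endpoint)
        table = AccuracyTable(tp=15 - int(r), fn=int(r), tn=30, fp=0)
        result = evaluate_interim(design_by_positives, table)
        assert result.sens.estimate == result.sens.boundary
        assert result.sens.decision is Decision.STOP_FUTILITY
        assert result.overall is Decision.STOP_FUTILITY

    def test_estimates_above_boundaries_continue(self, design_by_positives):
        table = AccuracyTable(tp=14, fn=1, tn=30, fp=0)
        result = evaluate_interim(design_by_positives, table)
        assert result.overall is Decision.CONTINUE

    def test_zero_denominator_endpoint_not_evaluable(self, design_by_positives):
        # no negatives accrued: specificity silent, sensitivity decides alone
        table = AccuracyTable(tp=2, fn=13, tn=0, fp=0)
        result = evaluate_interim(design_by_positives, table)
        assert result.spec.decision is Decision.NOT_EVALUABLE
        assert result.overall is Decision.STOP_FUTILITY

    def test_dash_boundary_never_stops(self, design_by_total):
        # 8 positives, all of them false negatives: boundary unattainable
        table = AccuracyTable(tp=0, fn=8, tn=17, fp=0)
        result = evaluate_interim(design_by_total, table)
        assert result.sens.decision is Decision.CONTINUE
        assert result.sens.boundary is not None

    def test_count_percent_duality(self, design_by_positives):
        # failures >= r  <=>  estimate <= 1 - r/n, exhaustively over n <= 200
        endpoint = design_by_positives.sens_endpoint
        for n in range(1, 201):
            r = futility_boundary_count(n, endpoint)
            if r is None or not isinstance(r, int):
                continue
            boundary = Fraction(n - r, n)
            for failures in range(0, n + 1):
                stop_by_count = failures >= r
                stop_by_percent = Fraction(n - failures, n) <= boundary
                assert stop_by_count == stop_by_percent


class TestMonitor:
    def test_example_dataset_decisions_by_total(self, design_by_total, cohort1):
        decisions = [r.overall for r in monitor(design_by_total, cohort1)]
        assert decisions == [
            Decision.CONTINUE,
            Decision.CONTINUE,
            Decision.STOP_FUTILITY,
        ]

    def test_short_accrual_yields_no_results(self, design_by_total, cohort1):
        assert monitor(design_by_total, cohort1.iloc[:10]) == []

    def test_prefix_stability_after_stop(self, design_by_total, cohort1):
        full = monitor(design_by_total, cohort1)
        truncated = monitor(design_by_total, cohort1.iloc[:150])
        assert full == truncated

    def test_both_rule_stops_are_subset_of_either(self, cohort1):
        either = make_design(0.35, "by_total", (25, 75, 150), 200, 0.75, 0.90)
        both = make_design(
            0.35, "by_total", (25, 75, 150), 200, 0.75, 0.90, futility_rule="both"
        )
        # evaluate every scheduled cut under both rules on identical tables:
        # a BOTH stop always implies an EITHER stop
        for upto in (25, 75, 150, 200):
            table = tabulate(cohort1, upto)
            stop_both = (
                evaluate_interim(both, table).overall is Decision.STOP_FUTILITY
            )
            stop_either = (
                evaluate_interim(either, table).overall is Decision.STOP_FUTILITY
            )
            assert not stop_both or stop_either

    def test_no_analyses_after_a_stop(self, design_by_total, cohort2):
        results = monitor(design_by_total, cohort2)
        assert [r.overall for r in results[:-1]] == [Decision.CONTINUE] * (
            len(results) - 1
        )
        assert results[-1].overall is Decision.STOP_FUTILITY
        assert results[-1].stage == 3  # stage 4 (final) never evaluated


class TestReadParticipants:
    def test_reads_well_formed_csv(self, tmp_path, cohort1):
        path = tmp_path / "cohort.csv"
        cohort1.to_csv(path, index=False)
        recs = read_participants(path)
        pd.testing.assert_frame_equal(recs, cohort1)

    def test_rejects_values_outside_binary(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("order,reference,index\n1,1,1\n2,2,0\n3,0,1\n")
        with pytest.raises(DataError, match=r"row\(s\) \[3\]"):
            read_participants(path)

    def test_rejects_missing_columns(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("order,truth\n1,0\n")
        with pytest.raises(DataError, match="missing column"):
            read_participants(path)

    def test_rejects_non_contiguous_order(self):
        recs = _records([1, 0], [1, 0])
        recs["order"] = [1, 3]
        with pytest.raises(DataError, match="contiguous"):
            monitor(
                make_design(0.5, "by_total", (2,), 4, 0.75, 0.75),
                recs,
            )
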