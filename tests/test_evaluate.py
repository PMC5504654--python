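"""Value orders, matched degrees, and cohort reporting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syndel import (
    AnswerRecord,
    MappingMatrix,
    SeverityFilter,
    ValidationError,
    assign_value_orders,
    bin_matched_degrees,
    compute_element_values,
    evaluate_condensed,
    group_matched_degree,
    integrated_matched_degree,
    match_record,
)
from syndel.evaluate import BIN_LABELS, ORDER_WEIGHTS, GroupMatch
from syndel.model import ConsistencyError, GROUPS


def values_series(registry, mapping):
    """Dense value series over all 47 elements from a sparse dict."""
    s = pd.Series(0.0, index=list(registry.indices))
    for k, v in mapping.items():
        s[k] = v
    s.name = "rv"
    return s


class TestAssignValueOrders:
    def test_group_maximum_gets_order_8(self, registry):
        v = values_series(registry, {25: 30.0, 28: 60.0})
        orders = assign_value_orders(v, registry)
        assert orders.orders[28] == 8
        assert orders.weights[28] == 1.0

    def test_half_of_group_maximum_gets_order_3(self, registry):
        v = values_series(registry, {25: 30.0, 28: 60.0})
        orders = assign_value_orders(v, registry)
        assert orders.orders[25] == 3  # ratio 0.5 in [0.4, 0.6)
        assert orders.weights[25] == 0.6

    @pytest.mark.parametrize(
        "ratio,order",
        [(1.0, 8), (0.95, 8), (0.9, 7), (0.85, 6), (0.8, 5), (0.6, 4),
         (0.4, 3), (0.2, 2), (0.1, 1)],
    )
    def test_order_table_boundaries(self, registry, ratio, order):
        v = values_series(registry, {26: 100.0 * ratio, 28: 100.0})
        orders = assign_value_orders(v, registry)
        assert orders.orders[26] == order

    def test_zero_value_gets_order_zero(self, registry):
        v = values_series(registry, {28: 60.0})
        orders = assign_value_orders(v, registry)
        assert orders.orders[25] == 0
        assert orders.weights[25] == 0.0

    def test_all_zero_group_all_orders_zero(self, registry):
        v = values_series(registry, {28: 60.0})  # only the disease-cause group scored
        orders = assign_value_orders(v, registry)
        for i in registry.group_indices("visceral"):
            assert orders.orders[i] == 0

    def test_scale_invariance(self, registry, rng):
        raw = values_series(registry, {i: x for i, x in
                                       zip(registry.evaluable_indices,
                                           rng.uniform(0, 50, size=45))})
        base = assign_value_orders(raw, registry)
        for c in (0.01, 3.0, 1e6):
            scaled = assign_value_orders(raw * c, registry)
            assert (scaled.orders == base.orders).all()

    def test_each_scored_group_has_an_order_8(self, registry, rng):
        raw = values_series(registry, {i: x for i, x in
                                       zip(registry.evaluable_indices,
                                           rng.uniform(1, 50, size=45))})
        orders = assign_value_orders(raw, registry)
        for g in GROUPS:
            assert orders.orders[list(registry.group_indices(g))].max() == 8


class TestGroupMatchedDegree:
    def test_identical_orders_match_perfectly(self, registry, rng):
        v = values_series(registry, {i: x for i, x in
                                     zip(registry.evaluable_indices,
                                         rng.uniform(1, 50, size=45))})
        orders = assign_value_orders(v, registry)
        for g in GROUPS:
            gm = group_matched_degree(orders, orders, g, registry)
            assert gm.mdg == 1.0
            assert gm.n_mismatched == 0

    def test_single_mismatch_weighted_by_reference_order(self, registry):
        # Eight-principle group: 6 evaluable elements; one mismatch whose
        # reference order is 4 (weight 0.7) gives (6 - 0.7) / 6.
        ref = values_series(registry, {1: 100.0, 2: 70.0})
        test = values_series(registry, {1: 100.0, 2: 95.0})
        ro = assign_value_orders(ref, registry)
        to = assign_value_orders(test, registry)
        assert ro.orders[2] == 4 and to.orders[2] == 8
        gm = group_matched_degree(ro, to, "eight_principle", registry)
        assert gm.n_mismatched == 1
        assert gm.mdg == pytest.approx((6 - 0.7) / 6)

    def test_total_mismatch_at_maximal_weight_gives_zero(self, registry):
        idx = list(registry.group_indices("eight_principle"))
        ref = values_series(registry, {i: 100.0 for i in idx})   # all order 8, weight 1
        test = values_series(registry, {idx[0]: 100.0,
                                        **{i: 50.0 for i in idx[1:]}})
        ro = assign_value_orders(ref, registry)
        to = assign_value_orders(test, registry)
        # force full mismatch: make test orders differ everywhere
        to.orders[idx[0]] = 4
        gm = group_matched_degree(ro, to, "eight_principle", registry)
        assert gm.n_mismatched == 6
        assert gm.mdg == pytest.approx(0.0)

    def test_vacuous_agreement_of_empty_groups(self, registry):
        v = values_series(registry, {28: 10.0})
        ro = assign_value_orders(v, registry)
        gm = group_matched_degree(ro, ro, "visceral", registry)
        assert gm.mdg == 1.0

    def test_weight_source_selects_the_penalty(self, registry):
        ref = values_series(registry, {1: 100.0, 2: 70.0})   # e2 order 4 (0.7)
        test = values_series(registry, {1: 100.0, 2: 95.0})  # e2 order 8 (1.0)
        ro, to = assign_value_orders(ref, registry), assign_value_orders(test, registry)
        by_ref = group_matched_degree(ro, to, "eight_principle", registry, "reference")
        by_test = group_matched_degree(ro, to, "eight_principle", registry, "test")
        by_max = group_matched_degree(ro, to, "eight_principle", registry, "max")
        assert by_ref.mismatch_sum == pytest.approx(0.7)
        assert by_test.mismatch_sum == pytest.approx(1.0)
        assert by_max.mismatch_sum == pytest.approx(1.0)

    def test_removing_a_mismatch_never_decreases_mdg(self, registry, rng):
        v1 = values_series(registry, {i: x for i, x in
                                      zip(registry.evaluable_indices, rng.uniform(1, 50, 45))})
        v2 = values_series(registry, {i: x for i, x in
                                      zip(registry.evaluable_indices, rng.uniform(1, 50, 45))})
        ro, to = assign_value_orders(v1, registry), assign_value_orders(v2, registry)
        for g in GROUPS:
            before = group_matched_degree(ro, to, g, registry).mdg
            fixed = to.orders.copy()
            mism = [i for i in registry.group_indices(g) if ro.orders[i] != to.orders[i]]
            if not mism:
                continue
            fixed[mism[0]] = ro.orders[mism[0]]
            to2 = type(to)(record_id=to.record_id, orders=fixed,
                           weights=fixed.map(ORDER_WEIGHTS).astype(float))
            after = group_matched_degree(ro, to2, g, registry).mdg
            assert after >= before - 1e-12


class TestIntegratedMatchedDegree:
    def test_perfect_groups_give_one(self):
        groups = [GroupMatch(g, cg, 0, 0.0, 1.0)
                  for g, cg in zip(GROUPS, (6, 7, 16, 16))]
        assert integrated_matched_degree(groups) == pytest.approx(1.0)

    def test_weighted_mean_of_group_degrees(self):
        mdgs = (1.0, 1.0, 1.0, 0.0)
        groups = [GroupMatch(g, cg, 0, 0.0, m)
                  for g, cg, m in zip(GROUPS, (6, 7, 16, 16), mdgs)]
        assert integrated_matched_degree(groups) == pytest.approx(29 / 45)

    def test_zero_groups_give_zero(self):
        groups = [GroupMatch(g, cg, cg, float(cg), 0.0)
                  for g, cg in zip(GROUPS, (6, 7, 16, 16))]
        assert integrated_matched_degree(groups) == pytest.approx(0.0)

    def test_inconsistent_counts_rejected(self):
        groups = [GroupMatch(g, 10, 0, 0.0, 1.0) for g in GROUPS]
        with pytest.raises(ConsistencyError):
            integrated_matched_degree(groups)


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=30))
def test_histogram_conserves_and_partitions(percents):
    counts = bin_matched_degrees(percents)
    assert counts.sum() == len(percents)
    assert list(counts.index) == list(BIN_LABELS)


@pytest.mark.parametrize(
    "pct,label",
    [(100.0, "[95, 100]"), (95.0, "[95, 100]"), (94.999, "[90, 95)"),
     (80.0, "[80, 85)"), (60.0, "[60, 65)"), (59.999, "[0, 60)"), (0.0, "[0, 60)")],
)
def test_histogram_bin_edges(pct, label):
    counts = bin_matched_degrees([pct])
    assert counts[label] == 1


class TestEvaluateCondensed:
    def test_self_comparison_is_perfect(self, cohort, matrix, registry):
        report = evaluate_condensed(cohort, matrix, matrix, registry=registry)
        assert all(rm.md == pytest.approx(1.0) for rm in report.records)
        assert report.histograms["integrated"]["[95, 100]"] == len(cohort)

    def test_histogram_matches_independent_recount(self, cohort, matrix, registry):
        from syndel import CondenseRule, condense_matrix

        condensed = condense_matrix(matrix, CondenseRule("symptom", "normal"))
        report = evaluate_condensed(cohort, matrix, condensed, registry=registry)
        # independent recount from the per-record table
        pcts = report.to_frame()["integrated"]
        recount = {label: 0 for label in BIN_LABELS}
        for p in pcts:
            for label, lo in zip(BIN_LABELS, (95, 90, 85, 80, 75, 70, 65, 60, 0)):
                if p >= lo:
                    recount[label] += 1
                    break
        assert dict(report.histograms["integrated"]) == recount
        assert report.histograms["integrated"].sum() == len(cohort)

    def test_severe_mode_covers_only_severe_records(self, small_matrix):
        qids = small_matrix.question_ids
        cohort = []
        for i in range(10):
            answers = {q: "C" for q in qids}
            if i < 3:
                answers[qids[0]] = "A"
            cohort.append(AnswerRecord(f"r{i}", "male", answers))
        report = evaluate_condensed(
            cohort, small_matrix, small_matrix, SeverityFilter("severe_only")
        )
        assert report.n_input == 10
        assert report.n_evaluated == 3

    def test_mismatched_dimensions_rejected(self, matrix, small_matrix, cohort):
        with pytest.raises(ValidationError):
            evaluate_condensed(cohort, matrix, small_matrix)
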