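"""Value-order assignment and matched-degree evaluation.

Quantitative element values are only meaningful relative to their
differentiation group: each evaluable element receives a *value order*
(an ordinal 1-8, or 0 when its value is zero) from the ratio of its
value to the group maximum, and each order carries a weight expressing
its diagnostic importance.

Agreement between the diagnoses produced by two mapping matrices is
measured per group by the matched degree

    MDG = (CG - sum over mismatched elements of SE_W) / CG

where CG is the number of evaluable elements in the group, an element
is mismatched when its value order differs between the two runs, and
SE_W is the order weight of the mismatched element (taken from the
reference run by default).  The integrated matched degree is the
group-size-weighted mean

    MD = sum over groups of MDG * CG / CT,        CT = 45.

Cohort-level results are reported as histograms of MD (in percent)
over the standard report bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    GROUPS,
    ConsistencyError,
    ElementRegistry,
    MappingMatrix,
    ValidationError,
    load_registry,
)
from .quantify import ElementValueVector, SeverityFilter, compute_element_values

__all__ = [
    "ORDER_RULES",
    "ORDER_WEIGHTS",
    "BIN_LABELS",
    "ValueOrderVector",
    "GroupMatch",
    "RecordMatch",
    "MatchReport",
    "assign_value_orders",
    "group_matched_degree",
    "match_record",
    "integrated_matched_degree",
    "bin_matched_degrees",
    "evaluate_condensed",
]

# (lo, lo_closed, hi, hi_closed, order): ratio of value to group maximum.
ORDER_RULES: tuple[tuple[float, bool, float, bool, int], ...] = (
    (0.95, True, 1.0, True, 8),
    (0.9, True, 0.95, False, 7),
    (0.85, True, 0.9, False, 6),
    (0.8, True, 0.85, False, 5),
    (0.6, True, 0.8, False, 4),
    (0.4, True, 0.6, False, 3),
    (0.2, True, 0.4, False, 2),
    (0.0, False, 0.2, False, 1),
)

#: Diagnostic weight of each value order; order 0 (zero value) weighs 0.
ORDER_WEIGHTS = {8: 1.0, 7: 0.95, 6: 0.9, 5: 0.8, 4: 0.7, 3: 0.6, 2: 0.4, 1: 0.2, 0: 0.0}

#: Report bins for matched degree in percent, top bin closed on both sides.
BIN_LABELS = (
    "[95, 100]",
    "[90, 95)",
    "[85, 90)",
    "[80, 85)",
    "[75, 80)",
    "[70, 75)",
    "[65, 70)",
    "[60, 65)",
    "[0, 60)",
)
_BIN_LOWER = (95, 90, 85, 80, 75, 70, 65, 60, 0)


def _order_of_ratio(r: float) -> int:
    for lo, lo_c, hi, hi_c, order in ORDER_RULES:
        above = r > lo or (lo_c and r == lo)
        below = r < hi or (hi_c and r == hi)
        if above and below:
            return order
    raise ValidationError(f"ratio {r!r} outside (0, 1]")


@dataclass
class ValueOrderVector:
    """Per-element value orders and order weights for one record."""

    record_id: str
    orders: pd.Series  # index: evaluable element indices, int orders 0..8
    weights: pd.Series  # same index, order weights

    def max_order(self) -> int:
        return int(self.orders.max())

    def elements_at_order(self, order: int) -> tuple[int, ...]:
        return tuple(int(i) for i in self.orders.index[self.orders == order])


def assign_value_orders(
    values: ElementValueVector | pd.Series,
    registry: Optional[ElementRegistry] = None,
) -> ValueOrderVector:
    """Assign value orders per differentiation group.

    For each group the maximum value among its evaluable elements sets
    the denominator; a zero value (or a wholly zero group) yields order
    0 with weight 0.  The assignment is invariant to rescaling all
    values by a positive constant.
    """
    registry = registry or load_registry()
    if isinstance(values, ElementValueVector):
        record_id, series = values.record_id, values.values
    else:
        record_id, series = str(values.name or ""), values
    idx = list(registry.evaluable_indices)
    missing = [i for i in idx if i not in series.index]
    if missing:
        raise ValidationError(f"values missing for evaluable elements {missing}")
    orders = pd.Series(0, index=idx, dtype=int)
    for group in GROUPS:
        gidx = list(registry.group_indices(group))
        v = series[gidx].astype(float)
        gmax = float(v.max())
        if gmax <= 0:
            continue
        for i in gidx:
            if v[i] > 0:
                orders[i] = _order_of_ratio(float(v[i]) / gmax)
    weights = orders.map(ORDER_WEIGHTS).astype(float)
    return ValueOrderVector(record_id=record_id, orders=orders, weights=weights)


@dataclass(frozen=True)
class GroupMatch:
    """Matched degree of one differentiation group."""

    group: str
    cg: int  # count of evaluable elements in the group
    n_mismatched: int
    mismatch_sum: float  # sum of SE_W over mismatched elements
    mdg: float


@dataclass
class RecordMatch:
    """Per-record match: four group results and the integrated degree."""

    record_id: str
    groups: dict[str, GroupMatch]
    md: float


def group_matched_degree(
    ref: ValueOrderVector,
    test: ValueOrderVector,
    group: str,
    registry: Optional[ElementRegistry] = None,
    weight_source: str = "reference",
) -> GroupMatch:
    """Matched degree of one group, reference orders as the standard.

    ``weight_source`` selects which run supplies the weight SE_W of a
    mismatched element: ``reference`` (default), ``test``, or ``max``
    (the larger of the two).
    """
    registry = registry or load_registry()
    if weight_source not in ("reference", "test", "max"):
        raise ValidationError(
            f"weight_source must be reference/test/max, got {weight_source!r}"
        )
    gidx = list(registry.group_indices(group))
    for vec, name in ((ref, "reference"), (test, "test")):
        absent = [i for i in gidx if i not in vec.orders.index]
        if absent:
            raise ValidationError(f"{name} orders missing elements {absent} of group {group}")
    mismatched = [i for i in gidx if int(ref.orders[i]) != int(test.orders[i])]
    if weight_source == "reference":
        contrib = sum(float(ref.weights[i]) for i in mismatched)
    elif weight_source == "test":
        contrib = sum(float(test.weights[i]) for i in mismatched)
    else:
        contrib = sum(max(float(ref.weights[i]), float(test.weights[i])) for i in mismatched)
    cg = len(gidx)
    mdg = (cg - contrib) / cg
    return GroupMatch(group=group, cg=cg, n_mismatched=len(mismatched), mismatch_sum=contrib, mdg=mdg)


def integrated_matched_degree(
    groups: Iterable[GroupMatch], ct: int = 45
) -> float:
    """Integrated matched degree: CG/CT-weighted mean of the group MDGs."""
    groups = list(groups)
    total = sum(g.cg for g in groups)
    if total != ct:
        raise ConsistencyError(f"group counts sum to {total}, expected CT = {ct}")
    return sum(g.mdg * g.cg / ct for g in groups)


def match_record(
    ref: ValueOrderVector,
    test: ValueOrderVector,
    registry: Optional[ElementRegistry] = None,
    weight_source: str = "reference",
) -> RecordMatch:
    """Compute all four group matches and the integrated MD for one record."""
    registry = registry or load_registry()
    groups = {
        g: group_matched_degree(ref, test, g, registry, weight_source) for g in GROUPS
    }
    md = integrated_matched_degree(groups.values(), ct=len(registry.evaluable_indices))
    return RecordMatch(record_id=ref.record_id, groups=groups, md=md)


def bin_matched_degrees(percents: Iterable[float]) -> pd.Series:
    """Count matched degrees (percent scale) into the report bins."""
    counts = pd.Series(0, index=list(BIN_LABELS), dtype=int)
    for p in percents:
        if not 0 <= p <= 100:
            raise ValidationError(f"matched degree percent {p!r} outside [0, 100]")
        for label, lo in zip(BIN_LABELS, _BIN_LOWER):
            if p >= lo:
                counts[label] += 1
                break
    return counts


@dataclass
class MatchReport:
    """Cohort-level evaluation of a condensed matrix against the original."""

    records: list[RecordMatch]
    histograms: dict[str, pd.Series]  # per group plus "integrated"
    n_input: int
    n_evaluated: int
    mode: str

    def to_frame(self) -> pd.DataFrame:
        """Per-record MDGs and MD as a tidy frame (percent scale)."""
        rows = []
        for rm in self.records:
            row = {"record_id": rm.record_id}
            for g, gm in rm.groups.items():
                row[g] = 100.0 * gm.mdg
            row["integrated"] = 100.0 * rm.md
            rows.append(row)
        return pd.DataFrame(rows)

    def histogram_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.histograms)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_input": self.n_input,
            "n_evaluated": self.n_evaluated,
            "records": [
                {
                    "record_id": rm.record_id,
                    "md": rm.md,
                    "groups": {g: gm.mdg for g, gm in rm.groups.items()},
                }
                for rm in self.records
            ],
            "histograms": {k: {b: int(v) for b, v in s.items()} for k, s in self.histograms.items()},
        }


def evaluate_condensed(
    cohort: Sequence,
    original: MappingMatrix,
    condensed: MappingMatrix,
    severity: Optional[SeverityFilter] = None,
    registry: Optional[ElementRegistry] = None,
    weight_source: str = "reference",
) -> MatchReport:
    """Evaluate a condensed matrix against the original over a cohort.

    Each record is quantified under both matrices, value orders are
    assigned to both, and the original-matrix orders serve as the
    reference.  Under ``severe_only`` the report covers only records
    with at least one severe answer.
    """
    severity = severity or SeverityFilter()
    registry = registry or load_registry()
    if set(original.question_ids) != set(condensed.question_ids) or set(
        original.element_indices
    ) != set(condensed.element_indices):
        raise ValidationError("original and condensed matrices must share dimensions")
    records: list[RecordMatch] = []
    n_input = 0
    for record in cohort:
        n_input += 1
        ref_values = compute_element_values(record, original, severity)
        if ref_values.flagged:
            continue
        test_values = compute_element_values(record, condensed, severity)
        ref_orders = assign_value_orders(ref_values, registry)
        test_orders = assign_value_orders(test_values, registry)
        records.append(match_record(ref_orders, test_orders, registry, weight_source))
    histograms = {
        g: bin_matched_degrees(100.0 * rm.groups[g].mdg for rm in records) for g in GROUPS
    }
    histograms["integrated"] = bin_matched_degrees(100.0 * rm.md for rm in records)
    return MatchReport(
        records=records,
        histograms=histograms,
        n_input=n_input,
        n_evaluated=len(records),
        mode=severity.mode,
    )
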