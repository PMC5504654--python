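"""Quantification of syndrome elements from questionnaire answers.

The quantitative value of element *e* for one record is the weighted
sum, over answered questions *q*, of ``answer_weight(q) * W[q, e]``
where *W* is the mapping-weight matrix.  The *overall health state*
uses all answers; the *major health state* restricts the sum to severe
answers (level A by default, optionally A and B).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    AnswerRecord,
    MappingMatrix,
    ValidationError,
    answer_weight,
)

__all__ = ["SeverityFilter", "ElementValueVector", "compute_element_values", "batch_quantify"]


@dataclass(frozen=True)
class SeverityFilter:
    """Which answers contribute to element values.

    ``all_symptoms`` keeps every answer (overall health state);
    ``severe_only`` keeps only answers in ``severe_levels`` (major
    health state).  Severe levels default to {A}; {A, B} is admissible.
    """

    mode: str = "all_symptoms"
    severe_levels: frozenset = frozenset({"A"})

    def __post_init__(self) -> None:
        if self.mode not in ("all_symptoms", "severe_only"):
            raise ValidationError(
                f"filter mode must be 'all_symptoms' or 'severe_only', got {self.mode!r}"
            )
        levels = frozenset(self.severe_levels)
        object.__setattr__(self, "severe_levels", levels)
        if not levels <= {"A", "B"}:
            raise ValidationError("severe_levels must be a subset of {'A', 'B'}")
        if self.mode == "severe_only" and not levels:
            raise ValidationError("severe_only filter requires at least one severe level")

    def passes(self, label: str) -> bool:
        return self.mode == "all_symptoms" or label in self.severe_levels


@dataclass
class ElementValueVector:
    """Per-element quantitative values for one record, with provenance."""

    record_id: str
    values: pd.Series  # index: element indices, float values
    scale: str
    mode: str
    flagged: bool = False  # severe_only record with no severe answer

    def __getitem__(self, element_index: int) -> float:
        return float(self.values[element_index])


def compute_element_values(
    record: AnswerRecord,
    matrix: MappingMatrix,
    severity: Optional[SeverityFilter] = None,
) -> ElementValueVector:
    """Score one record against a mapping matrix.

    Raises :class:`ValidationError` listing the offending ids if the
    record answers a question absent from the matrix.
    """
    severity = severity or SeverityFilter()
    missing = sorted(set(record.answers) - set(matrix.question_ids))
    if missing:
        raise ValidationError(
            f"record {record.record_id!r} answers questions not in the matrix: {missing}"
        )
    w = pd.Series(0.0, index=matrix.weights.index)
    for q, label in record.answers.items():
        if severity.passes(label):
            w[q] = answer_weight(label)
    values = matrix.weights.T @ w
    values.name = record.record_id
    flagged = severity.mode == "severe_only" and not any(
        label in severity.severe_levels for label in record.answers.values()
    )
    return ElementValueVector(
        record_id=record.record_id,
        values=values,
        scale=matrix.scale,
        mode=severity.mode,
        flagged=flagged,
    )


def batch_quantify(
    cohort: Iterable[AnswerRecord],
    matrix: MappingMatrix,
    severity: Optional[SeverityFilter] = None,
) -> list[ElementValueVector]:
    """Order-preserving quantification of a cohort.

    Under ``severe_only``, records with no severe answer come back with
    ``flagged=True``: they carry no information about the major health
    state and are dropped by downstream evaluation.
    """
    severity = severity or SeverityFilter()
    out = []
    for record in cohort:
        try:
            out.append(compute_element_values(record, matrix, severity))
        except ValidationError as err:
            raise ValidationError(f"record {record.record_id!r}: {err}") from err
    return out
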