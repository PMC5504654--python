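"""Synthetic mapping matrices, answer cohorts, and record screening.

The diagnostic knowledge base (the original mapping-weight matrix) and
the clinical cohort behind the method are not publicly deposited, so
this module generates statistically shaped stand-ins: a sparse positive
matrix on the (0, 100) weight scale linking every directly-scored
element to several questions, and a cohort of categorical answer
records whose sex split and severe-answer prevalence mirror a field
cohort (a male:female split near 301:369 and roughly 80% of records
containing at least one severe answer).

All generation is driven by ``numpy.random.default_rng`` seeds, so a
spec plus a seed reproduces the same data on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    ANSWER_LEVELS,
    AnswerRecord,
    ElementRegistry,
    MappingMatrix,
    ValidationError,
    load_registry,
)

__all__ = [
    "MatrixSpec",
    "CohortSpec",
    "generate_matrix",
    "generate_cohort",
    "screen_cohort",
    "ExcludedRecord",
]

#: Default per-question answer-level probabilities.  Mostly D (no
#: symptom), a thin tail of severe answers: with 177 questions the
#: chance of at least one A per record is about 0.81, matching a
#: majority-severe cohort (544 of 670).  A convenience default, not an
#: empirical estimate.
DEFAULT_ANSWER_PROBS = {"A": 0.0094, "B": 0.05, "C": 0.12, "D": 0.8206}


@dataclass
class MatrixSpec:
    """Shape parameters of a synthetic original-weight matrix."""

    n_questions: int = 177
    links_per_question: tuple[int, int] = (3, 8)  # inclusive range
    weight_low: float = 1.0
    weight_high: float = 99.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.links_per_question
        if not (1 <= lo <= hi):
            raise ValidationError("links_per_question must satisfy 1 <= lo <= hi")
        if not (0 < self.weight_low < self.weight_high < 100):
            raise ValidationError("weights must satisfy 0 < low < high < 100")
        if self.n_questions < 1:
            raise ValidationError("n_questions must be positive")


@dataclass
class CohortSpec:
    """Shape parameters of a synthetic answer cohort."""

    n_records: int = 670
    sex_ratio: float = 301 / 670  # fraction of male records
    answer_level_probabilities: dict = field(
        default_factory=lambda: dict(DEFAULT_ANSWER_PROBS)
    )
    inquiry_time_model: tuple[float, float] = (900.0, 180.0)  # mean, sd seconds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise ValidationError("n_records must be non-negative")
        if not 0 <= self.sex_ratio <= 1:
            raise ValidationError("sex_ratio must lie in [0, 1]")
        probs = self.answer_level_probabilities
        if set(probs) != set(ANSWER_LEVELS):
            raise ValidationError(f"probabilities must cover exactly {ANSWER_LEVELS}")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"answer probabilities sum to {total}, expected 1")
        if any(p < 0 for p in probs.values()):
            raise ValidationError("answer probabilities must be non-negative")


def generate_matrix(
    spec: MatrixSpec, registry: Optional[ElementRegistry] = None
) -> MappingMatrix:
    """Draw a sparse original-scale mapping matrix.

    Each question links to a random handful of directly-scored
    elements with uniform weights; columns for the two composite
    elements (deficiency and excess) stay empty, and every other
    element is guaranteed at least one link.
    """
    registry = registry or load_registry()
    rng = np.random.default_rng(spec.seed)
    evaluable = list(registry.evaluable_indices)
    lo, hi = spec.links_per_question
    if hi > len(evaluable):
        raise ValidationError(
            f"links_per_question upper bound {hi} exceeds the {len(evaluable)} "
            "directly-scored elements"
        )
    questions = list(range(1, spec.n_questions + 1))
    w = pd.DataFrame(
        0.0, index=pd.Index(questions, name="question_id"), columns=list(registry.indices)
    )
    for q in questions:
        k = int(rng.integers(lo, hi + 1))
        cols = rng.choice(evaluable, size=k, replace=False)
        w.loc[q, cols] = rng.uniform(spec.weight_low, spec.weight_high, size=k)
    # guarantee coverage of every directly-scored element
    for e in evaluable:
        if not (w[e] > 0).any():
            q = int(rng.choice(questions))
            w.loc[q, e] = float(rng.uniform(spec.weight_low, spec.weight_high))
    return MappingMatrix(w, scale="original")


def generate_cohort(
    spec: CohortSpec, question_ids: Sequence[int]
) -> list[AnswerRecord]:
    """Draw a cohort of answer records over one questionnaire.

    Answer levels are i.i.d. across questions per the spec's level
    probabilities; inquiry times are normal (truncated at zero).
    """
    if not question_ids:
        raise ValidationError("question_ids must be nonempty")
    rng = np.random.default_rng(spec.seed)
    qids = [int(q) for q in question_ids]
    levels = list(ANSWER_LEVELS)
    p = [spec.answer_level_probabilities[l] for l in levels]
    mean_t, sd_t = spec.inquiry_time_model
    cohort = []
    for i in range(spec.n_records):
        sex = "male" if rng.random() < spec.sex_ratio else "female"
        drawn = rng.choice(levels, size=len(qids), p=p)
        seconds = max(0.0, float(rng.normal(mean_t, sd_t)))
        cohort.append(
            AnswerRecord(
                record_id=f"r{i + 1:04d}",
                sex=sex,
                answers={q: str(a) for q, a in zip(qids, drawn)},
                inquiry_seconds=seconds,
            )
        )
    return cohort


@dataclass(frozen=True)
class ExcludedRecord:
    """A screened-out record with its exclusion reason tag.

    Tags: ``a`` no symptoms (every answer D); ``b`` inquiry time below
    the required minimum; ``c`` all answers at one identical level.
    """

    record: AnswerRecord
    reason: str


def screen_cohort(
    cohort: Iterable[AnswerRecord], min_inquiry_seconds: float
) -> tuple[list[AnswerRecord], list[ExcludedRecord]]:
    """Partition a cohort into kept records and tagged exclusions.

    There is no field standard for "too short" an inquiry, so the
    minimum time is a required parameter.  A record matching several
    criteria is tagged with the first that applies (a, then b, then c);
    an all-D record is therefore tagged ``a`` even though it is also
    uniform.
    """
    kept: list[AnswerRecord] = []
    excluded: list[ExcludedRecord] = []
    for record in cohort:
        labels = set(record.answers.values())
        if labels == {"D"}:
            excluded.append(ExcludedRecord(record, "a"))
        elif record.inquiry_seconds is not None and record.inquiry_seconds < min_inquiry_seconds:
            excluded.append(ExcludedRecord(record, "b"))
        elif len(labels) == 1:
            excluded.append(ExcludedRecord(record, "c"))
        else:
            kept.append(record)
    return kept, excluded
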