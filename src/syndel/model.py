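"""Core domain vocabulary for syndrome-element differentiation.

Traditional Chinese medicine (TCM) decomposes a patient's health state
into *syndrome elements* — atomic diagnostic units such as a disease
location ("Spleen") or a disease nature ("Dampness").  This module holds
the fixed registry of the 47 elements used by the inquiry-based
quantification method, the four differentiation groups they belong to,
the four-level answer scale of the inquiry questionnaire, and the two
container types everything downstream consumes: the mapping-weight
matrix (questions x elements) and a subject's answer record.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "DomainError",
    "ConsistencyError",
    "GROUPS",
    "ANSWER_LEVELS",
    "ANSWER_WEIGHTS",
    "CONDENSED_WEIGHTS",
    "NOT_DIRECTLY_MAPPED",
    "answer_weight",
    "SyndromeElement",
    "ElementRegistry",
    "load_registry",
    "Question",
    "questionnaire",
    "MappingMatrix",
    "AnswerRecord",
]


class ValidationError(ValueError):
    """Input violates a structural contract (bad label, missing column...)."""


class DomainError(ValueError):
    """A numeric value lies outside the domain a rule table covers."""


class ConsistencyError(ValueError):
    """Internally inconsistent aggregate (e.g. group counts that do not sum)."""


# The four classical differentiation groups, keyed by canonical name.
GROUPS = ("eight_principle", "disease_cause", "qi_blood_fluid_humor", "visceral")

# Four-level answer scale: severity/frequency fused into one weight.
ANSWER_LEVELS = ("A", "B", "C", "D")
ANSWER_WEIGHTS = {"A": 1.0, "B": 0.618, "C": 0.382, "D": 0.0}

# Admissible condensed mapping weights (fuzzy superset; normal uses {2,4,6,10}).
CONDENSED_WEIGHTS = frozenset({2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0})

# Deficiency (7) and excess (8) are composite judgements, not scored
# directly from inquiry answers; they are excluded from evaluation.
NOT_DIRECTLY_MAPPED = frozenset({7, 8})


def answer_weight(label: str) -> float:
    """Return the quantitative weight of an answer level.

    A = severe/always -> 1, B = a little severe/sometimes -> 0.618,
    C = not severe/seldom -> 0.382, D = none/never -> 0.
    """
    try:
        return ANSWER_WEIGHTS[label]
    except KeyError:
        raise ValidationError(
            f"unknown answer level {label!r}; expected one of {ANSWER_LEVELS}"
        ) from None


# index -> (name, group).  Group 1 = eight-principle (1-8), group 2 =
# disease-cause (25-31), group 3 = qi-blood-fluid-humor (9-24),
# group 4 = visceral (32-47).
_ELEMENTS: dict[int, tuple[str, str]] = {
    1: ("Yang deficiency", "eight_principle"),
    2: ("Yin deficiency", "eight_principle"),
    3: ("Yang hyperactivity", "eight_principle"),
    4: ("Yang floating", "eight_principle"),
    5: ("Exterior", "eight_principle"),
    6: ("Half-exterior half-interior", "eight_principle"),
    7: ("Deficiency", "eight_principle"),
    8: ("Excess", "eight_principle"),
    9: ("Qi deficiency", "qi_blood_fluid_humor"),
    10: ("Qi stagnation", "qi_blood_fluid_humor"),
    11: ("Qi sinking", "qi_blood_fluid_humor"),
    12: ("Insecurity of qi", "qi_blood_fluid_humor"),
    13: ("Qi counterflow", "qi_blood_fluid_humor"),
    14: ("Blood deficiency", "qi_blood_fluid_humor"),
    15: ("Blood stasis", "qi_blood_fluid_humor"),
    16: ("Blood heat", "qi_blood_fluid_humor"),
    17: ("Blood cold", "qi_blood_fluid_humor"),
    18: ("Stirring blood", "qi_blood_fluid_humor"),
    19: ("Stirring wind", "qi_blood_fluid_humor"),
    20: ("Phlegm", "qi_blood_fluid_humor"),
    21: ("Retained fluid", "qi_blood_fluid_humor"),
    22: ("Water retention", "qi_blood_fluid_humor"),
    23: ("Fluid depletion", "qi_blood_fluid_humor"),
    24: ("Essence deficiency", "qi_blood_fluid_humor"),
    25: ("External wind", "disease_cause"),
    26: ("Cold", "disease_cause"),
    27: ("Summerheat", "disease_cause"),
    28: ("Dampness", "disease_cause"),
    29: ("Dryness", "disease_cause"),
    30: ("Fire-heat", "disease_cause"),
    31: ("Food accumulation", "disease_cause"),
    32: ("Liver", "visceral"),
    33: ("Gallbladder", "visceral"),
    34: ("Lung", "visceral"),
    35: ("Large intestine", "visceral"),
    36: ("Spleen", "visceral"),
    37: ("Stomach", "visceral"),
    38: ("Kidney", "visceral"),
    39: ("Bladder", "visceral"),
    40: ("Heart", "visceral"),
    41: ("Small intestine", "visceral"),
    42: ("Heart spirit", "visceral"),
    43: ("Chest and diaphragm", "visceral"),
    44: ("Uterus", "visceral"),
    45: ("Sinew and bone", "visceral"),
    46: ("Skin", "visceral"),
    47: ("Meridian-collateral", "visceral"),
}


@dataclass(frozen=True)
class SyndromeElement:
    """One atomic diagnostic unit (a location or a nature)."""

    index: int
    name: str
    group: str

    @property
    def label(self) -> str:
        """Short label used in formal contexts and diagrams, e.g. ``e28``."""
        return f"e{self.index}"


@dataclass(frozen=True)
class ElementRegistry:
    """The fixed, ordered registry of the 47 syndrome elements.

    ``evaluable`` excludes deficiency (7) and excess (8), leaving 45
    elements that are scored directly from inquiry answers; per-group
    evaluable counts are 6 / 7 / 16 / 16.
    """

    elements: tuple[SyndromeElement, ...]

    def __post_init__(self) -> None:
        indices = [e.index for e in self.elements]
        if len(set(indices)) != len(indices):
            raise ConsistencyError("duplicate element indices in registry")
        if len(self.elements) != 47:
            raise ConsistencyError(f"registry must hold 47 elements, got {len(self.elements)}")

    def __iter__(self):
        return iter(self.elements)

    def __getitem__(self, index: int) -> SyndromeElement:
        for e in self.elements:
            if e.index == index:
                return e
        raise KeyError(index)

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(e.index for e in self.elements)

    @property
    def evaluable(self) -> tuple[SyndromeElement, ...]:
        return tuple(e for e in self.elements if e.index not in NOT_DIRECTLY_MAPPED)

    @property
    def evaluable_indices(self) -> tuple[int, ...]:
        return tuple(e.index for e in self.evaluable)

    def group_indices(self, group: str, evaluable_only: bool = True) -> tuple[int, ...]:
        """Element indices belonging to one differentiation group."""
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}; expected one of {GROUPS}")
        pool = self.evaluable if evaluable_only else self.elements
        return tuple(e.index for e in pool if e.group == group)


def load_registry() -> ElementRegistry:
    """Build the canonical 47-element registry."""
    return ElementRegistry(
        tuple(SyndromeElement(i, name, group) for i, (name, group) in sorted(_ELEMENTS.items()))
    )


@dataclass(frozen=True)
class Question:
    """One inquiry question about a symptom or sign."""

    id: int
    text: str = ""
    sex_applicability: str = "both"  # male | female | both

    def __post_init__(self) -> None:
        if self.sex_applicability not in ("male", "female", "both"):
            raise ValidationError(
                f"sex_applicability must be male/female/both, got {self.sex_applicability!r}"
            )


#: Question counts of the inquiry instrument per sex.
N_QUESTIONS = {"male": 177, "female": 194}


def questionnaire(sex: str) -> tuple[Question, ...]:
    """Return the inquiry questionnaire resolved for one sex.

    The male instrument has 177 questions; the female one extends it to
    194.  Question texts are free-form placeholders — only the counts
    and the sex split are part of the method's contract.
    """
    if sex not in ("male", "female"):
        raise ValidationError(f"sex must be 'male' or 'female', got {sex!r}")
    n = N_QUESTIONS[sex]
    out = []
    for i in range(1, n + 1):
        applicability = "both" if i <= N_QUESTIONS["male"] else "female"
        out.append(Question(id=i, text=f"question {i}", sex_applicability=applicability))
    return tuple(out)


class MappingMatrix:
    """Mapping weights linking inquiry questions to syndrome elements.

    Stored dense as a float DataFrame (rows = question ids, columns =
    element indices); 0 encodes "no mapping".  ``scale`` is either
    ``original`` (positive weights strictly inside (0, 100)) or
    ``condensed`` (positive weights drawn from {2, 3, 4, 5, 6, 8, 10}).
    """

    def __init__(self, weights: pd.DataFrame, scale: str = "original") -> None:
        if scale not in ("original", "condensed"):
            raise ValidationError(f"scale must be 'original' or 'condensed', got {scale!r}")
        w = weights.astype(float)
        w.index.name = "question_id"
        w.columns = [int(c) for c in w.columns]
        self.weights = w
        self.scale = scale
        self.validate()

    def validate(self) -> None:
        w = self.weights
        if w.index.has_duplicates:
            raise ValidationError("duplicate question ids in matrix")
        if len(set(w.columns)) != len(w.columns):
            raise ValidationError("duplicate element columns in matrix")
        vals = w.to_numpy()
        if np.isnan(vals).any():
            raise ValidationError("matrix contains missing values")
        if (vals < 0).any():
            raise ValidationError("matrix weights must be non-negative")
        pos = vals[vals > 0]
        if self.scale == "original":
            if pos.size and (pos.max() >= 100.0):
                raise ValidationError(
                    "original-scale weights must lie strictly below 100"
                )
        else:
            bad = set(np.unique(pos)) - set(CONDENSED_WEIGHTS)
            if bad:
                raise ValidationError(
                    f"condensed-scale weights must be in {sorted(CONDENSED_WEIGHTS)}; got {sorted(bad)}"
                )

    @property
    def question_ids(self) -> tuple[int, ...]:
        return tuple(int(q) for q in self.weights.index)

    @property
    def element_indices(self) -> tuple[int, ...]:
        return tuple(int(c) for c in self.weights.columns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MappingMatrix):
            return NotImplemented
        return self.scale == other.scale and self.weights.equals(other.weights)

    def __repr__(self) -> str:
        n_q, n_e = self.weights.shape
        nnz = int((self.weights.to_numpy() > 0).sum())
        return f"MappingMatrix({n_q} questions x {n_e} elements, {nnz} links, scale={self.scale})"

    @classmethod
    def from_long(
        cls,
        entries: Iterable[tuple[int, int, float]],
        question_ids: Optional[Iterable[int]] = None,
        element_indices: Optional[Iterable[int]] = None,
        scale: str = "original",
    ) -> "MappingMatrix":
        """Build a matrix from (question_id, element_index, weight) triples."""
        entries = list(entries)
        seen: set[tuple[int, int]] = set()
        for q, e, _ in entries:
            if (q, e) in seen:
                raise ValidationError(f"duplicate (question, element) pair ({q}, {e})")
            seen.add((q, e))
        qs = sorted(question_ids) if question_ids is not None else sorted({q for q, _, _ in entries})
        es = sorted(element_indices) if element_indices is not None else sorted({e for _, e, _ in entries})
        w = pd.DataFrame(0.0, index=pd.Index(qs, name="question_id"), columns=es)
        for q, e, v in entries:
            w.loc[q, e] = v
        return cls(w, scale=scale)

    def to_long(self) -> pd.DataFrame:
        """Nonzero entries as a (question_id, element_index, weight) frame."""
        stacked = self.weights.stack()
        stacked = stacked[stacked > 0]
        out = stacked.rename("weight").reset_index()
        out.columns = ["question_id", "element_index", "weight"]
        return out


@dataclass
class AnswerRecord:
    """One subject's categorical answers to the inquiry questionnaire."""

    record_id: str
    sex: str
    answers: Mapping[int, str]
    inquiry_seconds: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.answers:
            raise ValidationError(f"record {self.record_id!r} has no answers")
        for q, label in self.answers.items():
            if label not in ANSWER_LEVELS:
                raise ValidationError(
                    f"record {self.record_id!r}: invalid answer {label!r} for question {q}"
                )
        if self.inquiry_seconds is not None and self.inquiry_seconds < 0:
            raise ValidationError(f"record {self.record_id!r}: negative inquiry time")

    @property
    def question_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.answers))

    def validate_against(self, questions: Iterable[Question]) -> None:
        """Check every applicable question has exactly one answer."""
        expected = {q.id for q in questions}
        got = set(self.answers)
        missing = expected - got
        extra = got - expected
        if missing or extra:
            raise ValidationError(
                f"record {self.record_id!r}: missing answers for {sorted(missing)}, "
                f"unexpected answers for {sorted(extra)}"
            )
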