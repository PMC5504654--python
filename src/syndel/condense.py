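"""Condensation of original mapping weights onto small ordinal scales.

Original mapping weights are empirical reals in (0, 100) that are hard
to read as TCM correlation degrees.  Condensation replaces each weight
with a small ordinal value carrying a qualitative meaning — 10 maximum
correlation, 2 minimum, 6/8 medium — under one of four rules:

* basis ``symptom``: quantize each weight by its absolute value;
* basis ``element``: quantize each weight by its ratio to the maximum
  weight of its element column (so association across the symptoms of
  one element is taken into account);
* granularity ``normal``: four output levels {2, 4, 6, 10};
* granularity ``fuzzy``: refined scale {2, 3, 4, 5, 6, 8, 10} with
  secondary levels (8, 5, 3) near interval boundaries.

Interval endpoints follow the printed rule tables literally, including
the fuzzy quirks (a value of exactly 10 falls in (8, 10] -> 3; a ratio
of exactly 0.2 falls in (0.15, 0.2] -> 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import NOT_DIRECTLY_MAPPED, DomainError, MappingMatrix, ValidationError

__all__ = [
    "CondenseRule",
    "RULE_NAMES",
    "quantize_value",
    "quantize_ratio",
    "condense_matrix",
]

#: Canonical rule names, mapping to (basis, granularity).
RULE_NAMES = {
    "symptom_normal": ("symptom", "normal"),
    "symptom_fuzzy": ("symptom", "fuzzy"),
    "element_normal": ("element", "normal"),
    "element_fuzzy": ("element", "fuzzy"),
}


@dataclass(frozen=True)
class CondenseRule:
    """One of the four condensation rules."""

    basis: str  # symptom | element
    granularity: str  # normal | fuzzy

    def __post_init__(self) -> None:
        if self.basis not in ("symptom", "element"):
            raise ValidationError(f"basis must be 'symptom' or 'element', got {self.basis!r}")
        if self.granularity not in ("normal", "fuzzy"):
            raise ValidationError(
                f"granularity must be 'normal' or 'fuzzy', got {self.granularity!r}"
            )

    @property
    def name(self) -> str:
        return f"{self.basis}_{self.granularity}"

    @classmethod
    def from_name(cls, name: str) -> "CondenseRule":
        try:
            basis, granularity = RULE_NAMES[name.lower()]
        except KeyError:
            raise ValidationError(
                f"unknown rule {name!r}; expected one of {sorted(RULE_NAMES)}"
            ) from None
        return cls(basis, granularity)


class _IntervalTable:
    """Disjoint intervals with explicit open/closed endpoints -> output."""

    def __init__(self, entries: Sequence[tuple[float, bool, float, bool, float]]):
        # entries: (lo, lo_closed, hi, hi_closed, out), order irrelevant
        self.entries = tuple(entries)

    def lookup(self, x: float) -> float:
        for lo, lo_c, hi, hi_c, out in self.entries:
            above = x > lo or (lo_c and x == lo)
            below = x < hi or (hi_c and x == hi)
            if above and below:
                return out
        raise DomainError(f"value {x!r} not covered by the interval table")


# Value-basis tables on (0, 100).
_VALUE_NORMAL = _IntervalTable([
    (40, True, 100, False, 10),
    (25, True, 40, False, 6),
    (10, False, 25, False, 4),
    (0, False, 10, True, 2),
])
_VALUE_FUZZY = _IntervalTable([
    (45, True, 100, False, 10),
    (40, True, 45, False, 8),
    (35, True, 40, False, 8),
    (30, True, 35, False, 6),
    (25, True, 30, False, 5),
    (20, True, 25, False, 5),
    (12, True, 20, False, 4),
    (10, False, 12, False, 3),
    (8, False, 10, True, 3),
    (0, False, 8, True, 2),
])

# Ratio-basis tables on (0, 1].
_RATIO_NORMAL = _IntervalTable([
    (0.6, True, 1, True, 10),
    (0.4, True, 0.6, False, 6),
    (0.2, True, 0.4, False, 4),
    (0, False, 0.2, False, 2),
])
_RATIO_FUZZY = _IntervalTable([
    (0.65, True, 1, True, 10),
    (0.6, True, 0.65, False, 8),
    (0.55, True, 0.6, False, 8),
    (0.45, True, 0.55, False, 6),
    (0.4, True, 0.45, False, 5),
    (0.35, True, 0.4, False, 5),
    (0.25, True, 0.35, False, 4),
    (0.2, False, 0.25, False, 3),
    (0.15, False, 0.2, True, 3),
    (0, False, 0.15, True, 2),
])


def quantize_value(v: float, granularity: str = "normal") -> float:
    """Condense an original weight (symptom basis) by its absolute value."""
    if not 0 < v < 100:
        raise DomainError(f"original weight must lie in (0, 100), got {v!r}")
    table = _VALUE_NORMAL if granularity == "normal" else _VALUE_FUZZY
    if granularity not in ("normal", "fuzzy"):
        raise ValidationError(f"granularity must be 'normal' or 'fuzzy', got {granularity!r}")
    return table.lookup(v)


def quantize_ratio(r: float, granularity: str = "normal") -> float:
    """Condense a weight/element-maximum ratio (element basis)."""
    if not 0 < r <= 1:
        raise DomainError(f"ratio must lie in (0, 1], got {r!r}")
    if granularity not in ("normal", "fuzzy"):
        raise ValidationError(f"granularity must be 'normal' or 'fuzzy', got {granularity!r}")
    table = _RATIO_NORMAL if granularity == "normal" else _RATIO_FUZZY
    return table.lookup(r)


def condense_matrix(matrix: MappingMatrix, rule: CondenseRule) -> MappingMatrix:
    """Apply one condensation rule to an original-scale matrix.

    Zeros (no mapping) stay zero and dimensions are preserved.  Under
    the element basis, a column with no positive weight has no maximum
    and is skipped with a warning.
    """
    if matrix.scale != "original":
        raise ValidationError("condense_matrix expects an original-scale matrix")
    w = matrix.weights
    out = w.copy()
    if rule.basis == "symptom":
        out = w.map(lambda v: quantize_value(v, rule.granularity) if v > 0 else 0.0)
    else:
        for col in w.columns:
            colmax = float(w[col].max())
            if colmax <= 0:
                if (w[col] != 0).any():  # pragma: no cover - guarded by validation
                    raise ValidationError(f"element column {col} has negative weights")
                if col not in NOT_DIRECTLY_MAPPED:  # 7/8 are empty by design
                    warnings.warn(
                        f"element column {col} has no positive weight; skipped under element basis",
                        stacklevel=2,
                    )
                continue
            out[col] = w[col].map(
                lambda v: quantize_ratio(v / colmax, rule.granularity) if v > 0 else 0.0
            )
    return MappingMatrix(out, scale="condensed")
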