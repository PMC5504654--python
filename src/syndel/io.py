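"""CSV/JSON readers and writers for matrices, cohorts, and contexts.

CSV is the canonical interchange (UTF-8, comma-separated, mandatory
header row); JSON mirrors carry metadata such as the matrix scale.
Readers validate and reject rather than silently coerce.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .aposd import FormalContext
from .model import (
    CONDENSED_WEIGHTS,
    AnswerRecord,
    MappingMatrix,
    ValidationError,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "matrix_to_json",
    "matrix_from_json",
    "read_records",
    "write_records",
    "read_context",
    "write_context",
]

PathLike = Union[str, Path]


def _infer_scale(weights: pd.DataFrame) -> str:
    vals = weights.to_numpy()
    pos = vals[vals > 0]
    if pos.size and set(np.unique(pos)) <= set(CONDENSED_WEIGHTS):
        return "condensed"
    return "original"


def write_matrix(matrix: MappingMatrix, path: PathLike, dialect: str = "wide") -> None:
    """Write a matrix as wide (full grid) or long (nonzero triples) CSV."""
    path = Path(path)
    if dialect == "wide":
        matrix.weights.to_csv(path)
    elif dialect == "long":
        matrix.to_long().to_csv(path, index=False)
    else:
        raise ValidationError(f"dialect must be 'wide' or 'long', got {dialect!r}")


def read_matrix(
    path: PathLike, dialect: str = "wide", scale: Optional[str] = None
) -> MappingMatrix:
    """Read a matrix CSV; scale is declared or inferred from the values.

    Inference: a matrix whose positive weights all belong to the
    condensed set {2, 3, 4, 5, 6, 8, 10} is condensed, else original.
    """
    path = Path(path)
    if dialect == "wide":
        df = pd.read_csv(path, index_col=0)
        try:
            df.index = df.index.astype(int)
            df.columns = [int(c) for c in df.columns]
        except (TypeError, ValueError) as err:
            raise ValidationError(f"{path}: non-integer question or element ids: {err}") from err
        weights = df.astype(float)
    elif dialect == "long":
        df = pd.read_csv(path)
        required = {"question_id", "element_index", "weight"}
        if not required <= set(df.columns):
            raise ValidationError(f"{path}: long dialect requires columns {sorted(required)}")
        dup = df.duplicated(subset=["question_id", "element_index"])
        if dup.any():
            lines = [int(i) + 2 for i in df.index[dup]]  # +2: header + 1-based
            raise ValidationError(f"{path}: duplicate (question, element) pairs at lines {lines}")
        weights = df.pivot(index="question_id", columns="element_index", values="weight").fillna(0.0)
        weights.index = weights.index.astype(int)
        weights.columns = [int(c) for c in weights.columns]
    else:
        raise ValidationError(f"dialect must be 'wide' or 'long', got {dialect!r}")
    if scale is None:
        scale = _infer_scale(weights)
    return MappingMatrix(weights, scale=scale)


def matrix_to_json(matrix: MappingMatrix) -> str:
    """JSON mirror carrying the scale alongside the nonzero entries."""
    entries = [
        {"question_id": int(q), "element_index": int(e), "weight": float(v)}
        for q, e, v in matrix.to_long().itertuples(index=False)
    ]
    return json.dumps({"scale": matrix.scale, "entries": entries}, indent=2)


def matrix_from_json(text: str) -> MappingMatrix:
    payload = json.loads(text)
    return MappingMatrix.from_long(
        [(d["question_id"], d["element_index"], d["weight"]) for d in payload["entries"]],
        scale=payload["scale"],
    )


def write_records(cohort: Sequence[AnswerRecord], path: PathLike) -> None:
    """One row per record: record_id, sex, inquiry_seconds, then one
    column per question id with values A/B/C/D."""
    qids = sorted({q for r in cohort for q in r.answers})
    rows = []
    for r in cohort:
        row: dict = {"record_id": r.record_id, "sex": r.sex, "inquiry_seconds": r.inquiry_seconds}
        for q in qids:
            row[str(q)] = r.answers.get(q, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_records(path: PathLike) -> list[AnswerRecord]:
    df = pd.read_csv(path, dtype=str)
    if "record_id" not in df.columns or "sex" not in df.columns:
        raise ValidationError(f"{path}: records CSV requires 'record_id' and 'sex' columns")
    meta = {"record_id", "sex", "inquiry_seconds"}
    qcols = [c for c in df.columns if c not in meta]
    try:
        qids = {c: int(c) for c in qcols}
    except ValueError as err:
        raise ValidationError(f"{path}: non-integer question column: {err}") from err
    cohort = []
    for lineno, (_, row) in enumerate(df.iterrows(), start=2):
        answers = {}
        for c in qcols:
            v = row[c]
            if isinstance(v, str) and v.strip():
                answers[qids[c]] = v.strip()
        seconds = row.get("inquiry_seconds")
        seconds = float(seconds) if isinstance(seconds, str) and seconds.strip() else None
        try:
            cohort.append(
                AnswerRecord(
                    record_id=str(row["record_id"]),
                    sex=str(row["sex"]),
                    answers=answers,
                    inquiry_seconds=seconds,
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path}, line {lineno}: {err}") from err
    return cohort


def write_context(context: FormalContext, path: PathLike, dialect: str = "cross") -> None:
    """Write a formal context as a cross-table (cells 1/blank) or as
    long-form (object, attribute) pairs."""
    path = Path(path)
    if dialect == "cross":
        df = context.to_frame().astype(object)
        df = df.where(df != 0, "")
        df = df.where(df != 1, "1")
        df.to_csv(path)
    elif dialect == "long":
        pairs = sorted(context.incidence)
        pd.DataFrame(pairs, columns=["object", "attribute"]).to_csv(path, index=False)
    else:
        raise ValidationError(f"dialect must be 'cross' or 'long', got {dialect!r}")


def read_context(path: PathLike, dialect: str = "cross") -> FormalContext:
    path = Path(path)
    if dialect == "cross":
        df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
        incidence = set()
        for o in df.index:
            for a in df.columns:
                cell = df.loc[o, a].strip()
                if cell == "1":
                    incidence.add((str(o), str(a)))
                elif cell not in ("", "0"):
                    raise ValidationError(
                        f"{path}: cell ({o}, {a}) must be 1 or blank, got {cell!r}"
                    )
        return FormalContext(
            objects=tuple(str(o) for o in df.index),
            attributes=tuple(str(a) for a in df.columns),
            incidence=frozenset(incidence),
        )
    if dialect == "long":
        df = pd.read_csv(path, dtype=str)
        if not {"object", "attribute"} <= set(df.columns):
            raise ValidationError(f"{path}: long dialect requires 'object' and 'attribute' columns")
        pairs = [(str(o), str(a)) for o, a in zip(df["object"], df["attribute"])]
        objects = list(dict.fromkeys(o for o, _ in pairs))
        attributes = list(dict.fromkeys(a for _, a in pairs))
        return FormalContext(
            objects=tuple(objects), attributes=tuple(attributes), incidence=frozenset(pairs)
        )
    raise ValidationError(f"dialect must be 'cross' or 'long', got {dialect!r}")
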