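"""End-to-end orchestration: simulate/load -> screen -> condense ->
evaluate -> knowledge discovery, with a manifest of every artifact."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .aposd import build_context, export_diagram, extract_combinations, generate_aposd
from .condense import CondenseRule, condense_matrix
from .evaluate import assign_value_orders, evaluate_condensed
from .io import read_matrix, read_records, write_context, write_matrix, write_records
from .model import MappingMatrix, ValidationError, load_registry, questionnaire
from .quantify import SeverityFilter, batch_quantify
from .synthdata import CohortSpec, MatrixSpec, generate_cohort, generate_matrix, screen_cohort

log = logging.getLogger("syndel")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either paths to an existing matrix/records CSV or a seed-driven
    synthetic setup (the default) may be supplied.
    """

    outdir: Path = Path("syndel_run")
    matrix_path: Optional[Path] = None
    records_path: Optional[Path] = None
    seed: int = 0
    n_records: int = 670
    n_questions: int = 177
    rules: tuple[str, ...] = ("symptom_normal", "symptom_fuzzy", "element_normal", "element_fuzzy")
    mode: str = "all_symptoms"
    severe_levels: tuple[str, ...] = ("A",)
    min_inquiry_seconds: Optional[float] = None
    weight_source: str = "reference"
    aposd_depth: int = 4
    aposd_min_support: int = 5

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        for rule in self.rules:
            CondenseRule.from_name(rule)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole workflow and write every artifact under ``outdir``.

    Returns a dict with the in-memory artifacts (matrices, reports,
    tree, combinations) plus the manifest.  Deterministic given the
    config: two runs with identical configs write byte-identical
    reports.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    registry = load_registry()
    written: list[Path] = []

    # --- inputs -------------------------------------------------------
    if config.matrix_path is not None:
        original = read_matrix(config.matrix_path)
        if original.scale != "original":
            raise ValidationError("pipeline requires an original-scale input matrix")
    else:
        original = generate_matrix(MatrixSpec(n_questions=config.n_questions, seed=config.seed), registry)
    if config.records_path is not None:
        cohort = read_records(config.records_path)
    else:
        qids = [q.id for q in questionnaire("male")][: config.n_questions]
        cohort = generate_cohort(
            CohortSpec(n_records=config.n_records, seed=config.seed + 1), qids
        )
    log.info("inputs: %d questions x %d elements, %d records",
             len(original.question_ids), len(original.element_indices), len(cohort))

    mpath = out / "matrix_original.csv"
    write_matrix(original, mpath)
    rpath = out / "records.csv"
    write_records(cohort, rpath)
    written += [mpath, rpath]

    # --- screening ----------------------------------------------------
    if config.min_inquiry_seconds is not None:
        kept, excluded = screen_cohort(cohort, config.min_inquiry_seconds)
        log.info("screening: %d kept, %d excluded", len(kept), len(excluded))
        spath = out / "screening.json"
        spath.write_text(json.dumps(
            {"kept": [r.record_id for r in kept],
             "excluded": [{"record_id": e.record.record_id, "reason": e.reason} for e in excluded]},
            indent=2))
        written.append(spath)
        cohort = kept

    severity = SeverityFilter(mode=config.mode, severe_levels=frozenset(config.severe_levels))

    # --- condensation + evaluation -----------------------------------
    reports = {}
    condensed_matrices = {}
    for rule_name in config.rules:
        rule = CondenseRule.from_name(rule_name)
        condensed = condense_matrix(original, rule)
        condensed_matrices[rule_name] = condensed
        cpath = out / f"matrix_{rule_name}.csv"
        write_matrix(condensed, cpath)
        written.append(cpath)
        report = evaluate_condensed(
            cohort, original, condensed, severity, registry, config.weight_source
        )
        reports[rule_name] = report
        log.info("rule %s: evaluated %d/%d records", rule_name, report.n_evaluated, report.n_input)
        jpath = out / f"report_{rule_name}.json"
        jpath.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        hpath = out / f"histogram_{rule_name}.csv"
        report.histogram_frame().to_csv(hpath, index_label="bin")
        written += [jpath, hpath]

    # --- knowledge discovery (original-matrix value orders) ----------
    values = batch_quantify(cohort, original, severity)
    orders = [
        (v.record_id, assign_value_orders(v, registry)) for v in values if not v.flagged
    ]
    context = build_context(orders)
    kpath = out / "context.csv"
    write_context(context, kpath)
    tree = generate_aposd(context)
    tpath = out / "aposd.json"
    tpath.write_text(export_diagram(tree, "json"))
    dpath = out / "aposd.dot"
    dpath.write_text(export_diagram(tree, "dot"))
    combos = extract_combinations(tree, depth=config.aposd_depth, min_support=config.aposd_min_support)
    bpath = out / "combinations.json"
    bpath.write_text(json.dumps(
        [{"chain": c.label, "support": c.support} for c in combos], indent=2))
    written += [kpath, tpath, dpath, bpath]
    log.info("knowledge discovery: %d objects, %d depth-%d combinations",
             len(context.objects), len(combos), config.aposd_depth)

    # --- manifest -----------------------------------------------------
    manifest = {
        "parameters": {
            "seed": config.seed,
            "n_records": config.n_records,
            "n_questions": config.n_questions,
            "rules": list(config.rules),
            "mode": config.mode,
            "severe_levels": sorted(config.severe_levels),
            "min_inquiry_seconds": config.min_inquiry_seconds,
            "weight_source": config.weight_source,
            "aposd_depth": config.aposd_depth,
            "aposd_min_support": config.aposd_min_support,
        },
        "artifacts": {p.name: _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "original": original,
        "cohort": cohort,
        "condensed": condensed_matrices,
        "reports": reports,
        "context": context,
        "tree": tree,
        "combinations": combos,
        "manifest": manifest,
    }
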