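"""Readers, writers and reporting for the screening pipeline.

Flat-file conventions: subjects as CSV with a fixed header, norms as
YAML or JSON, prognostic tables as CSV carrying both full-precision and
display values, prediction traces as JSONL plus a human-readable
summary.  Numbers use decimal points; decimal commas (a likely hazard
in source spreadsheets from this domain) are rejected with a clear
message rather than silently misparsed.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from .classify import DecisionConfig, PredictionTrace
from .errors import ValidationError
from .indices import (CRITERIA, AgeNorm, CriterionProfile, Group, NormTable,
                      Status, SubjectRecord, WeightNorm)
from .prognostic import PrognosticTable

logger = logging.getLogger(__name__)

SUBJECT_HEADER = (
    "subject_id", "group", "age", "body_length", "body_weight",
    "chest_circumference", "vlc_actual", "biceps_tense", "biceps_rest",
    "stange", "genchi", "splits", "crab", "forward_bend")

_STATUS_CELL = {Status.PRESENT: "1", Status.ABSENT: "0", Status.MISSING: "NA"}


@dataclass(frozen=True)
class RowError:
    """One rejected CSV row: 1-based line number and reason."""

    line: int
    message: str


def _parse_float(field: str, cell: str) -> Optional[float]:
    cell = cell.strip()
    if not cell:
        return None
    if "," in cell:
        raise ValidationError(
            f"{field}: decimal commas are not accepted ({cell!r}); "
            "use a decimal point")
    try:
        return float(cell)
    except ValueError as exc:
        raise ValidationError(f"{field}: not a number ({cell!r})") from exc


def read_subjects(path) -> tuple[list[SubjectRecord], list[RowError]]:
    """Read subject records from CSV.

    A malformed header is a hard error; malformed rows are collected in
    the returned error list (with line numbers) and the run continues.
    """
    with Path(path).open(encoding="utf-8", newline="") as handle:
        rows = list(csv.reader(handle))
    if not rows or not any(cell.strip() for cell in rows[0]):
        raise ValidationError(f"{path}: empty subjects file")
    header = tuple(cell.strip() for cell in rows[0])
    if header != SUBJECT_HEADER:
        raise ValidationError(
            f"{path}: header must be exactly "
            f"{','.join(SUBJECT_HEADER)!r}, got {','.join(header)!r}")
    records: list[SubjectRecord] = []
    errors: list[RowError] = []
    for lineno, raw in enumerate(rows[1:], start=2):
        if not any(cell.strip() for cell in raw):
            continue
        cells = [cell.strip() for cell in raw]
        if len(cells) != len(SUBJECT_HEADER):
            errors.append(RowError(lineno,
                                   f"expected {len(SUBJECT_HEADER)} cells, "
                                   f"got {len(cells)}"))
            continue
        row = dict(zip(SUBJECT_HEADER, cells))
        try:
            if not row["subject_id"]:
                raise ValidationError("subject_id: must not be empty")
            group = Group(row["group"]) if row["group"] else None
            records.append(SubjectRecord(
                subject_id=row["subject_id"], group=group,
                **{name: _parse_float(name, row[name])
                   for name in SUBJECT_HEADER[2:]}))
        except (ValidationError, ValueError) as exc:
            errors.append(RowError(lineno, str(exc)))
    for error in errors:
        logger.warning("%s:%d: %s", path, error.line, error.message)
    return records, errors


def write_subjects(records: Sequence[SubjectRecord], path) -> None:
    """Write subject records to CSV (missing values as empty cells)."""
    out = [",".join(SUBJECT_HEADER)]
    for record in records:
        cells = [record.subject_id,
                 record.group.value if record.group else ""]
        for name in SUBJECT_HEADER[2:]:
            value = getattr(record, name)
            cells.append("" if value is None else repr(value))
        out.append(",".join(cells))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def read_norms(path) -> NormTable:
    """Load a norms table from YAML (or JSON — YAML is a superset)."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: norms file must be a mapping")
    try:
        weight = tuple(WeightNorm(float(e["min_height"]),
                                  float(e["max_height"]),
                                  float(e["M"]), float(e["delta_R"]))
                       for e in raw["weight_norms"])
        stange = tuple(AgeNorm(float(e["min_age"]), float(e["max_age"]),
                               float(e["value"]))
                       for e in raw["stange_norm"])
        genchi = tuple(AgeNorm(float(e["min_age"]), float(e["max_age"]),
                               float(e["value"]))
                       for e in raw["genchi_norm"])
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{path}: malformed norms file: {exc}") from exc
    return NormTable(weight, stange, genchi)


def write_norms(norms: NormTable, path) -> None:
    payload = {
        "weight_norms": [
            {"min_height": n.min_height, "max_height": n.max_height,
             "M": n.M, "delta_R": n.delta_R} for n in norms.weight_norms],
        "stange_norm": [
            {"min_age": n.min_age, "max_age": n.max_age, "value": n.value}
            for n in norms.stange_norm],
        "genchi_norm": [
            {"min_age": n.min_age, "max_age": n.max_age, "value": n.value}
            for n in norms.genchi_norm],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False),
                          encoding="utf-8")


def write_profiles(profiles: Sequence[CriterionProfile], path) -> None:
    """Export criterion profiles: subject_id plus nine 1/0/NA columns."""
    out = [",".join(("subject_id",) + CRITERIA)]
    for profile in profiles:
        out.append(",".join(
            [profile.subject_id]
            + [_STATUS_CELL[profile.statuses[c]] for c in CRITERIA]))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def trace_to_dict(trace: PredictionTrace) -> dict:
    """JSON-serialisable view of a trace, with deterministic field order."""
    return {
        "subject_id": trace.subject_id,
        "outcome": trace.outcome.value,
        "stopping_step": trace.stopping_step,
        "final_sum": trace.final_sum,
        "threshold": trace.threshold,
        "steps": [{"criterion_id": s.criterion_id,
                   "status": s.status.value,
                   "coefficient": s.coefficient,
                   "cumulative": s.cumulative} for s in trace.steps],
        "skipped": list(trace.skipped),
    }


def write_report(traces: Sequence[PredictionTrace], table: PrognosticTable,
                 config: DecisionConfig, out_dir) -> tuple[Path, Path]:
    """Write per-subject JSONL traces and a human-readable summary.

    Returns the two paths written.  Output is deterministic: identical
    inputs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    jsonl_path = out_dir / "predictions.jsonl"
    summary_path = out_dir / "summary.txt"

    with jsonl_path.open("w", encoding="utf-8") as handle:
        for trace in traces:
            handle.write(json.dumps(trace_to_dict(trace)) + "\n")

    outcome_counts: dict[str, int] = {"success": 0, "low_probability": 0,
                                      "uncertain": 0}
    for trace in traces:
        outcome_counts[trace.outcome.value] += 1
    lines = [
        "Sequential screening report",
        f"subjects: {len(traces)}",
        f"threshold: +/-{config.threshold_points:g} decibans "
        f"(alpha = {config.alpha:g})",
        "",
        "Outcomes:",
    ]
    for outcome, count in outcome_counts.items():
        lines.append(f"  {outcome}: {count}")
    lines += ["", "Table rows (criterion: presence / absence / "
                  "informativeness):"]
    for row in table:
        lines.append(f"  {row.criterion_id}: {row.pc_presence_display:+.1f} / "
                     f"{row.pc_absence_display:+.1f} / "
                     f"{row.informativeness_display:.2f}")
    summary_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return jsonl_path, summary_path
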