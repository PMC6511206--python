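"""Automated detectors for the 12-item data-quality defect checklist.

The checklist covers documentation and structure (missing codebook,
codebook/dataset inconsistencies, inaccurate file format, unanalyzable
structure), analysis-plan coverage (missing outcome / analytic variables),
and cell-level entry errors judged against the codebook (missing, uncoded,
miscoded, embedded, implausible, unformatted values).

A dataset scores one point per distinct checklist item present, giving a
0–12 score regardless of how many individual cells exhibit an item.  Each
cell contributes at most one item, resolved by the fixed precedence
MISSING > EMBEDDED > UNCODED > MISCODED > IMPLAUSIBLE > UNFORMATTED.

All detectors are deterministic and codebook-driven: no fuzzy matching, no
repair, no imputation.  Their output is a :class:`DefectProfile` carrying
both the binary per-item presence and a cell-level evidence trail
(:class:`Finding`).
"""

from __future__ import annotations

import csv
import enum
import json
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .model import (
    ParseFlag,
    StudyMeta,
    StudySubmission,
    VariableKind,
    VariableSpec,
)

__all__ = [
    "DefectItem",
    "SUBMISSION_LEVEL_ITEMS",
    "CheckConfig",
    "Finding",
    "DefectProfile",
    "check_structural",
    "check_plan_variables",
    "check_values",
    "run_checklist",
    "write_findings_csv",
    "write_findings_json",
]


class DefectItem(enum.Enum):
    """The 12 checklist items, in stable order (used for scoring and Pareto)."""

    MISSING_CODEBOOK = "missing-codebook"
    CODEBOOK_INCONSISTENCY = "codebook-inconsistency"
    INACCURATE_FORMAT = "inaccurate-format"
    UNANALYZABLE_STRUCTURE = "unanalyzable-structure"
    MISSING_OUTCOME_VARS = "missing-outcome-variables"
    MISSING_ANALYTIC_VARS = "missing-analytic-variables"
    MISSING_VALUES = "missing-values"
    UNCODED_VALUES = "uncoded-values"
    MISCODED_VALUES = "miscoded-values"
    EMBEDDED_VALUES = "embedded-values"
    IMPLAUSIBLE_VALUES = "implausible-values"
    UNFORMATTED_VALUES = "unformatted-values"

    @property
    def order(self) -> int:
        return list(DefectItem).index(self)


#: Items attached to the submission as a whole (no variable/row evidence).
SUBMISSION_LEVEL_ITEMS = frozenset(
    {
        DefectItem.MISSING_CODEBOOK,
        DefectItem.INACCURATE_FORMAT,
        DefectItem.UNANALYZABLE_STRUCTURE,
    }
)

_INACCURATE_FORMAT_FLAGS = {
    ParseFlag.RAGGED_ROWS,
    ParseFlag.DUPLICATE_COLUMN_NAMES,
    ParseFlag.BLANK_HEADER_CELLS,
}
_UNANALYZABLE_FLAGS = {
    ParseFlag.REPEATED_HEADER_ROWS,
    ParseFlag.BLANK_ROW_BLOCKS,
}


@dataclass(frozen=True)
class CheckConfig:
    """Site-configurable conventions the detectors apply.

    missing_sentinels: cell texts read as missing (after stripping), in
        addition to the empty string.
    embedded_delimiters: characters that join multiple packed values in one
        scalar cell (``"120/80"``).
    value_unit_pattern: regex for a value+unit pair packed in one cell
        (``"45 kg"``).
    missing_threshold: minimum count of missing cells in a required variable
        before MISSING_VALUES is raised (default 1: any missing cell).
    """

    missing_sentinels: tuple[str, ...] = ("", "NA", "N/A", ".")
    embedded_delimiters: tuple[str, ...] = ("/", ";", ",")
    value_unit_pattern: str = r"^[+-]?\d+(?:\.\d+)?\s*[A-Za-z]+$"
    dash_range_pattern: str = r"^\d+(?:\.\d+)?\s*-\s*\d+(?:\.\d+)?$"
    missing_threshold: int = 1

    def is_missing(self, cell: Optional[str]) -> bool:
        if cell is None:
            return True
        return cell.strip() in self.missing_sentinels


DEFAULT_CONFIG = CheckConfig()

# canonical plain-number text: no decoration, no separators, no padding
_CANONICAL_NUMBER = re.compile(r"^[+-]?\d+(?:\.\d+)?$")


def _parse_number(text: str) -> Optional[float]:
    try:
        return float(text)
    except ValueError:
        return None


@dataclass
class Finding:
    """One piece of evidence for a checklist item.

    Cell-level findings carry the variable and 0-based row index;
    submission-level items (missing codebook, inaccurate format,
    unanalyzable structure) carry neither.
    """

    item: DefectItem
    variable: Optional[str] = None
    row_index: Optional[int] = None
    observed: Optional[str] = None
    explanation: str = ""


@dataclass
class DefectProfile:
    """Audit result for one submission: items present, evidence, 0–12 score."""

    submission_id: str
    present_items: frozenset[DefectItem]
    findings: list[Finding]
    score: int
    meta: StudyMeta

    @classmethod
    def from_findings(
        cls, submission_id: str, findings: Sequence[Finding], meta: StudyMeta
    ) -> "DefectProfile":
        present = frozenset(f.item for f in findings)
        return cls(
            submission_id=submission_id,
            present_items=present,
            findings=list(findings),
            score=len(present),
            meta=meta,
        )


# ---------------------------------------------------------------------------
# Structural checks
# ---------------------------------------------------------------------------

def check_structural(submission: StudySubmission) -> list[Finding]:
    """Documentation and structure checks.

    - MISSING_CODEBOOK: no codebook accompanied the dataset.
    - CODEBOOK_INCONSISTENCY: a dataset column the codebook does not
      describe, a required codebook variable with no dataset column, or a
      coded variable none of whose observed values is a permitted code.
    - INACCURATE_FORMAT: ragged rows, duplicate column names, or blank
      header cells.
    - UNANALYZABLE_STRUCTURE: repeated header rows or interleaved blank-row
      blocks, or a multi-point study with no recognisable subject-identifier
      column (none declared ``identifier`` in the codebook and the first
      column is not all-unique).
    """
    findings: list[Finding] = []
    ds = submission.dataset
    cb = submission.codebook

    if cb is None:
        findings.append(
            Finding(
                item=DefectItem.MISSING_CODEBOOK,
                explanation="no codebook (data dictionary) submitted with the dataset",
            )
        )
    else:
        described = set(cb.names)
        for col in dict.fromkeys(ds.columns):  # preserve order, dedupe
            if col not in described:
                findings.append(
                    Finding(
                        item=DefectItem.CODEBOOK_INCONSISTENCY,
                        variable=col,
                        observed=col,
                        explanation=f"dataset column {col!r} is not described in the codebook",
                    )
                )
        for v in cb.variables:
            if v.required and v.name not in ds.columns:
                findings.append(
                    Finding(
                        item=DefectItem.CODEBOOK_INCONSISTENCY,
                        variable=v.name,
                        explanation=f"required codebook variable {v.name!r} has no dataset column",
                    )
                )
        for v in cb.variables:
            if v.kind is not VariableKind.CODED or v.name not in ds.columns:
                continue
            idx = ds.column_index(v.name)
            observed = {
                c.strip()
                for r in range(ds.n_rows)
                if (c := ds.cell(r, idx)) is not None
                and not DEFAULT_CONFIG.is_missing(c)
            }
            if observed and observed.isdisjoint(v.code_domain or {}):
                findings.append(
                    Finding(
                        item=DefectItem.CODEBOOK_INCONSISTENCY,
                        variable=v.name,
                        observed=",".join(sorted(observed)[:5]),
                        explanation=(
                            f"no observed value of {v.name!r} belongs to its code domain"
                        ),
                    )
                )

    bad_format = ds.parse_flags & _INACCURATE_FORMAT_FLAGS
    if bad_format:
        findings.append(
            Finding(
                item=DefectItem.INACCURATE_FORMAT,
                observed=",".join(sorted(f.value for f in bad_format)),
                explanation="dataset file format anomalies: "
                + ", ".join(sorted(f.value for f in bad_format)),
            )
        )

    unanalyzable = ds.parse_flags & _UNANALYZABLE_FLAGS
    reason = None
    if unanalyzable:
        reason = "structural anomalies: " + ", ".join(
            sorted(f.value for f in unanalyzable)
        )
    elif submission.meta.capture.value == "multi-point":
        has_id_var = cb is not None and any(
            v.kind is VariableKind.IDENTIFIER and v.name in ds.columns
            for v in cb.variables
        )
        if not has_id_var:
            first = [
                ds.cell(r, 0) for r in range(ds.n_rows) if ds.cell(r, 0) is not None
            ]
            if len(set(first)) != len(first) or not first:
                reason = (
                    "multi-point study without a subject-identifier column "
                    "(no identifier variable declared; first column not unique)"
                )
    if reason:
        findings.append(
            Finding(item=DefectItem.UNANALYZABLE_STRUCTURE, explanation=reason)
        )
    return findings


def check_plan_variables(submission: StudySubmission) -> list[Finding]:
    """One finding per analysis-plan variable absent from the dataset columns."""
    findings: list[Finding] = []
    cols = set(submission.dataset.columns)
    for name in submission.plan.outcome_variables:
        if name not in cols:
            findings.append(
                Finding(
                    item=DefectItem.MISSING_OUTCOME_VARS,
                    variable=name,
                    explanation=f"outcome variable {name!r} missing from the dataset",
                )
            )
    for name in submission.plan.analytic_variables:
        if name not in cols:
            findings.append(
                Finding(
                    item=DefectItem.MISSING_ANALYTIC_VARS,
                    variable=name,
                    explanation=f"analytic variable {name!r} missing from the dataset",
                )
            )
    return findings


# ---------------------------------------------------------------------------
# Cell-level checks
# ---------------------------------------------------------------------------

def _classify_cell(
    cell: str, var: VariableSpec, config: CheckConfig
) -> Optional[tuple[DefectItem, str]]:
    """Assign at most one defect item to a non-missing cell.

    Precedence (after MISSING, handled by the caller):
    EMBEDDED > UNCODED > MISCODED > IMPLAUSIBLE > UNFORMATTED.
    """
    text = cell.strip()

    # embedded: several values packed into one scalar cell
    if var.kind in (VariableKind.NUMERIC, VariableKind.CODED):
        for delim in config.embedded_delimiters:
            if delim in text:
                parts = [p for p in text.split(delim)]
                if len(parts) >= 2 and all(p.strip() for p in parts):
                    return (
                        DefectItem.EMBEDDED_VALUES,
                        f"multiple values packed with {delim!r}",
                    )
        if re.match(config.value_unit_pattern, text):
            return (DefectItem.EMBEDDED_VALUES, "value with embedded unit")
        if re.match(config.dash_range_pattern, text):
            return (DefectItem.EMBEDDED_VALUES, "range packed into one cell")

    if var.kind is VariableKind.CODED:
        domain = var.code_domain or {}
        if text in domain:
            return None
        num = _parse_number(text)
        if num is not None:
            numeric_codes = set()
            for code in domain:
                c = _parse_number(code)
                if c is not None:
                    numeric_codes.add(c)
            if num in numeric_codes:
                return None
            return (
                DefectItem.MISCODED_VALUES,
                f"code {text!r} outside the permitted set "
                f"{{{','.join(domain)}}}",
            )
        return (
            DefectItem.UNCODED_VALUES,
            f"free text {text!r} where a code from "
            f"{{{','.join(domain)}}} was expected",
        )

    if var.kind is VariableKind.NUMERIC:
        num = _parse_number(text)
        if num is None:
            return (
                DefectItem.UNFORMATTED_VALUES,
                f"non-numeric entry {cell!r} in a numeric variable",
            )
        if var.plausible_range is not None:
            lo, hi = var.plausible_range
            if not (lo <= num <= hi):
                return (
                    DefectItem.IMPLAUSIBLE_VALUES,
                    f"value {num:g} outside plausible range [{lo:g}, {hi:g}]",
                )
        if cell != text or not _CANONICAL_NUMBER.match(text):
            return (
                DefectItem.UNFORMATTED_VALUES,
                f"numeric entry {cell!r} carries non-numeric decoration",
            )
        return None

    if var.kind is VariableKind.DATE and var.format_pattern:
        try:
            datetime.strptime(text, var.format_pattern)
        except ValueError:
            return (
                DefectItem.UNFORMATTED_VALUES,
                f"date {text!r} does not match declared layout "
                f"{var.format_pattern!r}",
            )
    return None


def check_values(
    submission: StudySubmission, config: CheckConfig = DEFAULT_CONFIG
) -> list[Finding]:
    """Cell-level entry-error checks, defined relative to the codebook.

    Requires a codebook: without one these checks are undefined, and the
    caller should run :func:`check_structural` only.
    """
    if submission.codebook is None:
        raise ValueError(
            "check_values requires a codebook; run check_structural only "
            "for codebook-less submissions"
        )
    ds = submission.dataset
    findings: list[Finding] = []
    missing_counts: dict[str, list[Finding]] = {}

    for var in submission.codebook.variables:
        idx = ds.column_index(var.name)
        if idx is None:
            continue
        for r in range(ds.n_rows):
            cell = ds.cell(r, idx)
            if config.is_missing(cell):
                if var.required:
                    missing_counts.setdefault(var.name, []).append(
                        Finding(
                            item=DefectItem.MISSING_VALUES,
                            variable=var.name,
                            row_index=r,
                            observed=cell,
                            explanation=f"missing value in required variable {var.name!r}",
                        )
                    )
                continue
            assert cell is not None
            hit = _classify_cell(cell, var, config)
            if hit is not None:
                item, why = hit
                findings.append(
                    Finding(
                        item=item,
                        variable=var.name,
                        row_index=r,
                        observed=cell,
                        explanation=why,
                    )
                )

    for var_findings in missing_counts.values():
        if len(var_findings) >= config.missing_threshold:
            findings.extend(var_findings)
    return findings


def run_checklist(
    submission: StudySubmission, config: CheckConfig = DEFAULT_CONFIG
) -> DefectProfile:
    """Run the full 12-item checklist and build the submission's profile.

    Cell-level checks are skipped when the codebook is absent (they are
    defined relative to it); the absence itself is already a finding.
    """
    findings = check_structural(submission)
    findings += check_plan_variables(submission)
    if submission.codebook is not None:
        findings += check_values(submission, config)
    return DefectProfile.from_findings(
        submission.submission_id, findings, submission.meta
    )


# ---------------------------------------------------------------------------
# Findings serialization
# ---------------------------------------------------------------------------

def _finding_record(submission_id: str, f: Finding) -> dict:
    return {
        "submission_id": submission_id,
        "item": f.item.value,
        "variable": f.variable or "",
        "row_index": "" if f.row_index is None else f.row_index,
        "observed": "" if f.observed is None else f.observed,
        "explanation": f.explanation,
    }


def write_findings_csv(
    profiles: Iterable[DefectProfile], path: Union[str, Path]
) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(
            fh,
            fieldnames=[
                "submission_id",
                "item",
                "variable",
                "row_index",
                "observed",
                "explanation",
            ],
        )
        w.writeheader()
        for p in profiles:
            for f in p.findings:
                w.writerow(_finding_record(p.submission_id, f))


def write_findings_json(
    profiles: Iterable[DefectProfile], path: Union[str, Path]
) -> None:
    records = [
        _finding_record(p.submission_id, f) for p in profiles for f in p.findings
    ]
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(records, fh, indent=2)
        fh.write("\n")
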