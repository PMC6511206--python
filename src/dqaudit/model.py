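"""Domain types and file I/O for dataset submissions.

A *submission* is the unit a biostatistics service audits before statistical
analysis: the tabular dataset itself, the accompanying codebook (data
dictionary), the analysis plan naming outcome and analytic variables, and
study-level metadata (design, coordinator, returning-investigator flags).

Cells are kept as raw text at read time.  All typing and validation against
the codebook happens downstream in :mod:`dqaudit.checks` — premature coercion
would destroy exactly the evidence those checks need (a ``"45 kg"`` in a
numeric column, a duplicated header).  For the same reason the dataset reader
never repairs anomalies: everything it tolerates is recorded in
``TabularDataset.parse_flags``.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "VariableKind",
    "VariableSpec",
    "CodebookSpec",
    "ParseFlag",
    "TabularDataset",
    "AnalysisPlan",
    "Capture",
    "Phase",
    "EntryMode",
    "StudyMeta",
    "StudySubmission",
    "read_dataset",
    "write_dataset",
    "read_codebook",
    "write_codebook",
    "read_plan",
    "write_plan",
    "read_meta",
    "write_meta",
    "read_submission",
]

PathLike = Union[str, Path]


class VariableKind(str, enum.Enum):
    """What a variable's cells are expected to contain."""

    CODED = "coded-categorical"
    NUMERIC = "numeric-continuous"
    DATE = "date"
    TEXT = "free-text"
    IDENTIFIER = "identifier"


class VariableSpec(BaseModel):
    """One codebook entry: name, type, permitted codes, plausible range.

    ``code_domain`` maps code (as entered in cells, e.g. ``"1"``) to its
    human label and is required exactly for coded-categorical variables.
    ``plausible_range`` is an inclusive (min, max) pair, only meaningful for
    numeric variables; units belong in ``label``.  ``format_pattern`` is a
    ``strptime``-style layout for date variables (e.g. ``"%Y-%m-%d"``).
    """

    name: str
    label: str = ""
    kind: VariableKind
    code_domain: Optional[dict[str, str]] = None
    plausible_range: Optional[tuple[float, float]] = None
    format_pattern: Optional[str] = None
    required: bool = True

    @field_validator("name")
    @classmethod
    def _name_nonempty(cls, v: str) -> str:
        if not v or not v.strip():
            raise ValueError("variable name must be non-empty")
        return v

    @model_validator(mode="after")
    def _kind_consistency(self) -> "VariableSpec":
        if self.kind is VariableKind.CODED:
            if not self.code_domain:
                raise ValueError(
                    f"variable {self.name!r}: code_domain required for "
                    "coded-categorical variables"
                )
        elif self.code_domain:
            raise ValueError(
                f"variable {self.name!r}: code_domain only allowed on "
                "coded-categorical variables"
            )
        if self.plausible_range is not None:
            if self.kind is not VariableKind.NUMERIC:
                raise ValueError(
                    f"variable {self.name!r}: plausible_range only allowed "
                    "on numeric-continuous variables"
                )
            lo, hi = self.plausible_range
            if not lo < hi:
                raise ValueError(
                    f"variable {self.name!r}: plausible_range min must be < max"
                )
        return self


class CodebookSpec(BaseModel):
    """A machine-readable data dictionary: an ordered list of variables."""

    variables: list[VariableSpec] = Field(min_length=1)
    version: str = ""

    @model_validator(mode="after")
    def _unique_names(self) -> "CodebookSpec":
        seen: set[str] = set()
        for v in self.variables:
            key = v.name.lower()
            if key in seen:
                raise ValueError(f"duplicate variable name in codebook: {v.name!r}")
            seen.add(key)
        return self

    def variable(self, name: str) -> Optional[VariableSpec]:
        """Look up a variable by exact name, or None."""
        for v in self.variables:
            if v.name == name:
                return v
        return None

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]


class ParseFlag(str, enum.Enum):
    """Reader-level anomalies tolerated (never repaired) while parsing CSV."""

    RAGGED_ROWS = "ragged-rows"
    DUPLICATE_COLUMN_NAMES = "duplicate-column-names"
    BLANK_HEADER_CELLS = "blank-header-cells"
    REPEATED_HEADER_ROWS = "repeated-header-rows"
    BLANK_ROW_BLOCKS = "blank-row-blocks"


@dataclass
class TabularDataset:
    """A raw tabular dataset: header, rows of raw cell text, parse anomalies.

    Rows may be ragged only when ``ParseFlag.RAGGED_ROWS`` is set.  Repeated
    header rows and interleaved blank-row blocks are dropped from ``rows``
    but recorded as flags so the structural checks still see them.
    """

    columns: list[str]
    rows: list[list[str]]
    parse_flags: set[ParseFlag] = field(default_factory=set)

    def __post_init__(self) -> None:
        n = len(self.columns)
        if any(len(r) != n for r in self.rows) and ParseFlag.RAGGED_ROWS not in self.parse_flags:
            raise ValueError("ragged rows present but RAGGED_ROWS flag not set")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column_index(self, name: str) -> Optional[int]:
        """Index of the first column with this name, or None."""
        try:
            return self.columns.index(name)
        except ValueError:
            return None

    def cell(self, row_index: int, col_index: int) -> Optional[str]:
        row = self.rows[row_index]
        return row[col_index] if col_index < len(row) else None


class AnalysisPlan(BaseModel):
    """The variables the investigator's analysis needs from the dataset."""

    outcome_variables: list[str] = Field(min_length=1)
    analytic_variables: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _disjoint(self) -> "AnalysisPlan":
        overlap = set(self.outcome_variables) & set(self.analytic_variables)
        if overlap:
            raise ValueError(
                f"outcome and analytic variables overlap: {sorted(overlap)}"
            )
        return self


class Capture(str, enum.Enum):
    SINGLE = "single-point"
    MULTI = "multi-point"


class Phase(str, enum.Enum):
    PRE = "pre"
    POST = "post"


class EntryMode(str, enum.Enum):
    MANUAL = "manual"
    ELECTRONIC = "electronic"


class StudyMeta(BaseModel):
    """Study-level stratifiers: design, team composition, submission phase."""

    capture: Capture
    coordinator_on_board: bool
    returning_pi: bool
    phase: Phase
    entry_mode: EntryMode = EntryMode.MANUAL


@dataclass
class StudySubmission:
    """Dataset + optional codebook + analysis plan + metadata.

    The codebook may legitimately be absent — that absence is itself one of
    the auditable defects, not an error of this container.
    """

    dataset: TabularDataset
    plan: AnalysisPlan
    meta: StudyMeta
    codebook: Optional[CodebookSpec] = None
    submission_id: str = ""


# ---------------------------------------------------------------------------
# Dataset CSV I/O
# ---------------------------------------------------------------------------

def _is_blank_row(row: list[str]) -> bool:
    return all(cell.strip() == "" for cell in row)


def read_dataset(path: PathLike) -> TabularDataset:
    """Read a CSV dataset, recording anomalies instead of repairing them.

    Dialect: comma-delimited, double-quote escaping, UTF-8, first row is the
    header.  Detected anomalies (all recorded in ``parse_flags``):

    - duplicate column names in the header
    - blank header cells
    - rows whose cell count differs from the header (ragged rows)
    - data rows identical to the header (repeated header rows; dropped)
    - blank rows followed by further data (blank-row blocks; dropped)
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        raw = list(csv.reader(fh))
    if not raw:
        raise ValueError(f"{path}: empty file, no header row")

    header = raw[0]
    flags: set[ParseFlag] = set()
    if len(set(header)) != len(header):
        flags.add(ParseFlag.DUPLICATE_COLUMN_NAMES)
    if any(c.strip() == "" for c in header):
        flags.add(ParseFlag.BLANK_HEADER_CELLS)

    body = raw[1:]
    # trailing fully-blank rows are a file-ending convention, not a defect
    while body and _is_blank_row(body[-1]):
        body.pop()

    rows: list[list[str]] = []
    for row in body:
        if _is_blank_row(row):
            flags.add(ParseFlag.BLANK_ROW_BLOCKS)
            continue
        if row == header:
            flags.add(ParseFlag.REPEATED_HEADER_ROWS)
            continue
        if len(row) != len(header):
            flags.add(ParseFlag.RAGGED_ROWS)
        rows.append(row)

    return TabularDataset(columns=header, rows=rows, parse_flags=flags)


def write_dataset(dataset: TabularDataset, path: PathLike) -> None:
    """Write a dataset to CSV, re-materialising flagged structural anomalies.

    Ragged rows, duplicate/blank header cells are representable directly.
    ``REPEATED_HEADER_ROWS`` / ``BLANK_ROW_BLOCKS`` are stripped from
    ``rows`` at read time, so the writer re-inserts one header copy (resp.
    one blank row) after the first data row; reading the file back then
    reproduces the same flags.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(dataset.columns)
        for i, row in enumerate(dataset.rows):
            w.writerow(row)
            if i == 0:
                if ParseFlag.REPEATED_HEADER_ROWS in dataset.parse_flags:
                    w.writerow(dataset.columns)
                if ParseFlag.BLANK_ROW_BLOCKS in dataset.parse_flags:
                    w.writerow([""] * len(dataset.columns))


# ---------------------------------------------------------------------------
# Codebook I/O — JSON document or flat CSV (one row per variable)
# ---------------------------------------------------------------------------

_CSV_FIELDS = ["name", "label", "kind", "codes", "min", "max", "format", "required"]


def _codebook_from_dict(doc: dict) -> CodebookSpec:
    return CodebookSpec.model_validate(doc)


def read_codebook(path: PathLike) -> CodebookSpec:
    """Read a codebook from JSON (``.json``) or flat CSV (anything else).

    The flat CSV dialect has one row per variable with columns
    ``name,label,kind,codes,min,max,format,required``; ``codes`` holds
    ``code=label`` pairs separated by ``|``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with path.open(encoding="utf-8") as fh:
            return _codebook_from_dict(json.load(fh))
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        variables = []
        for row in reader:
            codes = row.get("codes") or ""
            code_domain = None
            if codes.strip():
                code_domain = {}
                for pair in codes.split("|"):
                    code, _, label = pair.partition("=")
                    code_domain[code.strip()] = label.strip()
            rng = None
            if (row.get("min") or "").strip() and (row.get("max") or "").strip():
                rng = (float(row["min"]), float(row["max"]))
            variables.append(
                dict(
                    name=row["name"],
                    label=row.get("label") or "",
                    kind=row["kind"],
                    code_domain=code_domain,
                    plausible_range=rng,
                    format_pattern=(row.get("format") or "").strip() or None,
                    required=(row.get("required") or "true").strip().lower()
                    in ("true", "1", "yes"),
                )
            )
    return _codebook_from_dict({"variables": variables, "version": ""})


def write_codebook(codebook: CodebookSpec, path: PathLike) -> None:
    """Write a codebook to JSON or flat CSV by file extension (round-trips)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with path.open("w", encoding="utf-8") as fh:
            json.dump(codebook.model_dump(mode="json"), fh, indent=2)
            fh.write("\n")
        return
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        w.writeheader()
        for v in codebook.variables:
            codes = ""
            if v.code_domain:
                codes = "|".join(f"{c}={l}" for c, l in v.code_domain.items())
            lo, hi = ("", "")
            if v.plausible_range is not None:
                lo, hi = (repr(v.plausible_range[0]), repr(v.plausible_range[1]))
            w.writerow(
                dict(
                    name=v.name,
                    label=v.label,
                    kind=v.kind.value,
                    codes=codes,
                    min=lo,
                    max=hi,
                    format=v.format_pattern or "",
                    required=str(v.required).lower(),
                )
            )


# ---------------------------------------------------------------------------
# Plan / metadata I/O (JSON)
# ---------------------------------------------------------------------------

def read_plan(path: PathLike) -> AnalysisPlan:
    with Path(path).open(encoding="utf-8") as fh:
        return AnalysisPlan.model_validate(json.load(fh))


def write_plan(plan: AnalysisPlan, path: PathLike) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(plan.model_dump(mode="json"), fh, indent=2)
        fh.write("\n")


def read_meta(path: PathLike) -> StudyMeta:
    with Path(path).open(encoding="utf-8") as fh:
        return StudyMeta.model_validate(json.load(fh))


def write_meta(meta: StudyMeta, path: PathLike) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(meta.model_dump(mode="json"), fh, indent=2)
        fh.write("\n")


def read_submission(
    dataset_path: PathLike,
    plan_path: PathLike,
    meta: Union[StudyMeta, PathLike],
    codebook_path: Optional[PathLike] = None,
    submission_id: str = "",
) -> StudySubmission:
    """Assemble a submission from files.

    A missing ``codebook_path`` (None) yields a submission without a codebook
    — a detectable defect, not an error.  A nonexistent dataset file is a
    fatal I/O error.  Reader-level anomalies end up in ``parse_flags``.
    """
    dataset = read_dataset(dataset_path)
    codebook = read_codebook(codebook_path) if codebook_path is not None else None
    plan = read_plan(plan_path)
    if not isinstance(meta, StudyMeta):
        meta = read_meta(meta)
    if not submission_id:
        submission_id = Path(dataset_path).stem
    return StudySubmission(
        dataset=dataset,
        plan=plan,
        meta=meta,
        codebook=codebook,
        submission_id=submission_id,
    )
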