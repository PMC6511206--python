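"""Synthetic clinical-research submissions with ground-truth defect labels.

Three layers:

* :func:`generate_clean` — a submission (dataset + codebook + plan + meta)
  that is defect-free by construction: every cell conforms to its variable
  specification, all plan variables exist, the codebook is attached.
* :func:`inject_defects` — mutate a clean submission to exhibit a chosen
  subset of the 12 checklist items, unambiguously (a miscode is exactly one
  above the largest permitted code; an implausible value is 10x the range
  maximum), returning the mutated copy and the injected truth set.
* :func:`build_fixture` — assemble a whole submission collection whose audit
  reproduces stated marginal targets exactly: band counts (zero / one /
  two-plus defects), total defect count, per-stratifier defective cross-tabs
  and a missing-codebook dataset count.  Defects beyond the two-per-dataset
  minimum in the two-plus band are allocated deterministically round-robin.

:data:`PAPER_PRE_SPEC` and :data:`PAPER_POST_SPEC` encode the reference
audit collections: 45 baseline submissions with 105 defects (bands 6/8/31,
20 missing codebooks, capture cross-tab [[6,15],[0,24]]) and 21 follow-up
submissions with 12 defects (bands 17/2/2, returning-PI cross-tab
[[14,0],[3,4]]).  The total defect counts are reconstructed from the printed
defects-per-unit values (2.33 x 45 and 0.57 x 21 — the unique integers whose
two-decimal quotients match); the per-dataset split inside the two-plus band
and the identities of most injected items are unprinted and therefore
synthetic.

Everything is seeded and bitwise-reproducible.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field as dc_field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .checks import DefectItem
from .conformance import DefectBand
from .model import (
    AnalysisPlan,
    Capture,
    CodebookSpec,
    EntryMode,
    ParseFlag,
    Phase,
    StudyMeta,
    StudySubmission,
    TabularDataset,
    VariableKind,
    VariableSpec,
    read_submission,
    write_codebook,
    write_dataset,
    write_meta,
    write_plan,
)

__all__ = [
    "GeneratorConfig",
    "InjectionSpec",
    "FixtureSpec",
    "PAPER_PRE_SPEC",
    "PAPER_POST_SPEC",
    "default_variable_menu",
    "generate_clean",
    "inject_defects",
    "build_fixture",
    "write_bundle",
    "read_bundle",
    "read_truth",
    "write_fixture",
]

_MODULUS = 2**31 - 1


def _child_seed(seed: int, index: int) -> int:
    return (seed * 1_000_003 + index * 7919 + 17) % _MODULUS


def default_variable_menu(capture: Capture = Capture.SINGLE) -> list[VariableSpec]:
    """A small clinical variable menu: identifiers, demographics, vitals,
    a visit date and coded outcomes.  Multi-point studies add a subject
    identifier and a visit number; the first column stays an all-unique
    record identifier in either design."""
    menu = [
        VariableSpec(name="record_id", label="record identifier", kind=VariableKind.IDENTIFIER),
    ]
    if capture is Capture.MULTI:
        menu += [
            VariableSpec(name="subject_id", label="subject identifier", kind=VariableKind.IDENTIFIER),
            VariableSpec(
                name="visit",
                label="visit number",
                kind=VariableKind.CODED,
                code_domain={"1": "baseline", "2": "follow-up 1", "3": "follow-up 2"},
            ),
        ]
    menu += [
        VariableSpec(name="age", label="age (years)", kind=VariableKind.NUMERIC, plausible_range=(18, 90)),
        VariableSpec(name="sex", label="sex", kind=VariableKind.CODED, code_domain={"1": "male", "2": "female"}),
        VariableSpec(name="sbp", label="systolic blood pressure (mmHg)", kind=VariableKind.NUMERIC, plausible_range=(50, 260)),
        VariableSpec(name="weight_kg", label="weight (kg)", kind=VariableKind.NUMERIC, plausible_range=(30, 200)),
        VariableSpec(name="height_cm", label="height (cm)", kind=VariableKind.NUMERIC, plausible_range=(100, 220)),
        VariableSpec(name="visit_date", label="visit date", kind=VariableKind.DATE, format_pattern="%Y-%m-%d"),
        VariableSpec(name="smoker", label="current smoker", kind=VariableKind.CODED, code_domain={"0": "no", "1": "yes"}),
        VariableSpec(name="outcome", label="primary outcome", kind=VariableKind.CODED, code_domain={"0": "no event", "1": "event"}),
    ]
    return menu


@dataclass
class GeneratorConfig:
    """Shape of one synthetic clean submission."""

    n_rows: int = 12
    capture: Capture = Capture.SINGLE
    seed: int = 0
    variable_menu: Optional[list[VariableSpec]] = None
    phase: Phase = Phase.PRE
    coordinator_on_board: bool = False
    returning_pi: bool = False
    entry_mode: EntryMode = EntryMode.MANUAL
    submission_id: str = ""

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise ValueError("n_rows must be >= 1")


def generate_clean(config: GeneratorConfig) -> StudySubmission:
    """Generate a defect-free submission (checklist score 0 by construction)."""
    menu = config.variable_menu or default_variable_menu(config.capture)
    codebook = CodebookSpec(variables=menu, version="1.0")
    rng = np.random.default_rng(config.seed)
    n = config.n_rows
    origin = date(2023, 1, 1)

    columns = [v.name for v in menu]
    rows: list[list[str]] = []
    for i in range(n):
        row: list[str] = []
        for v in menu:
            if v.name == "record_id":
                row.append(f"R{i + 1:04d}")
            elif v.name == "subject_id":
                row.append(f"S{i // 3 + 1:03d}")
            elif v.name == "visit":
                row.append(str(i % 3 + 1))
            elif v.kind is VariableKind.CODED:
                row.append(str(rng.choice(sorted(v.code_domain))))
            elif v.kind is VariableKind.NUMERIC:
                lo, hi = v.plausible_range or (0, 100)
                # keep a margin inside the plausible range
                span = hi - lo
                val = lo + 0.1 * span + rng.random() * 0.8 * span
                row.append(f"{val:.1f}" if v.name == "weight_kg" else str(int(round(val))))
            elif v.kind is VariableKind.DATE:
                row.append((origin + timedelta(days=int(rng.integers(0, 365)))).strftime(v.format_pattern or "%Y-%m-%d"))
            else:
                row.append(f"note {i + 1}")
        rows.append(row)

    dataset = TabularDataset(columns=columns, rows=rows)
    plan = AnalysisPlan(
        outcome_variables=["outcome"], analytic_variables=["height_cm", "smoker"]
    )
    meta = StudyMeta(
        capture=config.capture,
        coordinator_on_board=config.coordinator_on_board,
        returning_pi=config.returning_pi,
        phase=config.phase,
        entry_mode=config.entry_mode,
    )
    return StudySubmission(
        dataset=dataset,
        plan=plan,
        meta=meta,
        codebook=codebook,
        submission_id=config.submission_id or f"synthetic-{config.seed}",
    )


# ---------------------------------------------------------------------------
# Defect injection
# ---------------------------------------------------------------------------

@dataclass
class InjectionSpec:
    """Which checklist items to inject and at what per-item intensity
    (number of affected cells / variables; default 1 each)."""

    items: frozenset[DefectItem]
    intensity: dict[DefectItem, int] = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.items = frozenset(self.items)
        for item, k in self.intensity.items():
            if k < 1:
                raise ValueError(f"intensity for {item} must be >= 1")

    def intensity_of(self, item: DefectItem) -> int:
        return self.intensity.get(item, 1)


#: Items a checklist audit cannot see when the codebook is absent.
_CODEBOOK_DEPENDENT = frozenset(
    {
        DefectItem.CODEBOOK_INCONSISTENCY,
        DefectItem.MISSING_VALUES,
        DefectItem.UNCODED_VALUES,
        DefectItem.MISCODED_VALUES,
        DefectItem.EMBEDDED_VALUES,
        DefectItem.IMPLAUSIBLE_VALUES,
        DefectItem.UNFORMATTED_VALUES,
    }
)

_CELL_ITEMS = (
    DefectItem.MISSING_VALUES,
    DefectItem.UNCODED_VALUES,
    DefectItem.MISCODED_VALUES,
    DefectItem.EMBEDDED_VALUES,
    DefectItem.IMPLAUSIBLE_VALUES,
    DefectItem.UNFORMATTED_VALUES,
)


def _pick_variable(codebook, used, predicate):
    for v in codebook.variables:
        if v.name in used:
            continue
        if predicate(v):
            return v
    return None


def inject_defects(
    submission: StudySubmission, spec: InjectionSpec
) -> tuple[StudySubmission, frozenset[DefectItem]]:
    """Return a mutated copy of a clean submission plus its truth set.

    Each injection is unambiguous by construction so the audit recovers the
    truth set exactly:

    - missing codebook: codebook detached
    - codebook inconsistency: an undocumented column appended
    - inaccurate format: the first column duplicated (duplicate header name)
    - unanalyzable structure: a repeated header row
    - missing outcome / analytic variables: the variable's column removed
      from both dataset and codebook
    - missing value: a required cell blanked
    - uncoded: non-numeric free text in a coded variable
    - miscoded: numeric code exactly one above the maximum permitted code
    - embedded: ``"120/80"`` in a numeric cell
    - implausible: 10x the plausible-range maximum
    - unformatted: a date in the wrong layout

    Raises ValueError naming the item when it cannot be injected on this
    submission (e.g. cell-level items combined with a detached codebook, or
    no variable of the required kind left to target).
    """
    if submission.codebook is None:
        raise ValueError("inject_defects requires a clean, codebook-bearing submission")
    bad = spec.items & _CODEBOOK_DEPENDENT if DefectItem.MISSING_CODEBOOK in spec.items else frozenset()
    if bad:
        names = ", ".join(sorted(i.value for i in bad))
        raise ValueError(
            f"cannot inject {names} together with missing-codebook: the "
            "checklist cannot observe codebook-dependent items without a codebook"
        )

    sub = copy.deepcopy(submission)
    rng = np.random.default_rng(spec.seed)
    used_vars: set[str] = set()
    ds = sub.dataset

    def pick_rows(k: int) -> list[int]:
        k = min(k, ds.n_rows)
        return sorted(int(r) for r in rng.choice(ds.n_rows, size=k, replace=False))

    def set_cells(var_name: str, value_of, k: int) -> None:
        idx = ds.column_index(var_name)
        assert idx is not None
        for r in pick_rows(k):
            ds.rows[r][idx] = value_of(ds.rows[r][idx])

    def remove_variable(name: str) -> None:
        idx = ds.column_index(name)
        if idx is not None:
            ds.columns.pop(idx)
            for row in ds.rows:
                if idx < len(row):
                    row.pop(idx)
        sub.codebook.variables = [v for v in sub.codebook.variables if v.name != name]

    # plan-variable removals first so cell-level targeting sees final columns
    if DefectItem.MISSING_OUTCOME_VARS in spec.items:
        k = spec.intensity_of(DefectItem.MISSING_OUTCOME_VARS)
        targets = sub.plan.outcome_variables[:k]
        if not targets:
            raise ValueError("missing-outcome-variables: plan names no outcome variable")
        for name in targets:
            remove_variable(name)
            used_vars.add(name)
    if DefectItem.MISSING_ANALYTIC_VARS in spec.items:
        k = spec.intensity_of(DefectItem.MISSING_ANALYTIC_VARS)
        targets = sub.plan.analytic_variables[:k]
        if not targets:
            raise ValueError("missing-analytic-variables: plan names no analytic variable")
        for name in targets:
            remove_variable(name)
            used_vars.add(name)

    in_dataset = lambda v: v.name in ds.columns  # noqa: E731

    for item in _CELL_ITEMS:
        if item not in spec.items:
            continue
        k = spec.intensity_of(item)
        if item is DefectItem.MISSING_VALUES:
            var = _pick_variable(
                sub.codebook,
                used_vars,
                lambda v: v.required and v.kind is not VariableKind.IDENTIFIER and in_dataset(v),
            )
            if var is None:
                raise ValueError("missing-values: no required non-identifier variable available")
            set_cells(var.name, lambda _: "", k)
        elif item is DefectItem.UNCODED_VALUES:
            var = _pick_variable(
                sub.codebook, used_vars, lambda v: v.kind is VariableKind.CODED and in_dataset(v)
            )
            if var is None:
                raise ValueError("uncoded-values: no coded variable available")
            set_cells(var.name, lambda _: "invalid_label", k)
        elif item is DefectItem.MISCODED_VALUES:

            def numeric_coded(v: VariableSpec) -> bool:
                if v.kind is not VariableKind.CODED or not in_dataset(v):
                    return False
                try:
                    [float(c) for c in v.code_domain or {}]
                except ValueError:
                    return False
                return True

            var = _pick_variable(sub.codebook, used_vars, numeric_coded)
            if var is None:
                raise ValueError("miscoded-values: no numerically coded variable available")
            bad_code = str(int(max(float(c) for c in var.code_domain)) + 1)
            set_cells(var.name, lambda _: bad_code, k)
        elif item is DefectItem.EMBEDDED_VALUES:
            var = _pick_variable(
                sub.codebook, used_vars, lambda v: v.kind is VariableKind.NUMERIC and in_dataset(v)
            )
            if var is None:
                raise ValueError("embedded-values: no numeric (scalar) variable available")
            set_cells(var.name, lambda _: "120/80", k)
        elif item is DefectItem.IMPLAUSIBLE_VALUES:
            var = _pick_variable(
                sub.codebook,
                used_vars,
                lambda v: v.kind is VariableKind.NUMERIC and v.plausible_range is not None and in_dataset(v),
            )
            if var is None:
                raise ValueError("implausible-values: no range-bounded numeric variable available")
            extreme = f"{10 * var.plausible_range[1]:g}"
            set_cells(var.name, lambda _: extreme, k)
        elif item is DefectItem.UNFORMATTED_VALUES:
            var = _pick_variable(
                sub.codebook,
                used_vars,
                lambda v: v.kind is VariableKind.DATE and v.format_pattern and in_dataset(v),
            )
            if var is not None:
                set_cells(var.name, lambda _: "31-12-2020", k)
            else:
                var = _pick_variable(
                    sub.codebook, used_vars, lambda v: v.kind is VariableKind.NUMERIC and in_dataset(v)
                )
                if var is None:
                    raise ValueError("unformatted-values: no date or numeric variable available")
                set_cells(var.name, lambda old: f" {old} ", k)
        used_vars.add(var.name)

    if DefectItem.CODEBOOK_INCONSISTENCY in spec.items:
        k = spec.intensity_of(DefectItem.CODEBOOK_INCONSISTENCY)
        for j in range(k):
            name = f"undocumented_{j + 1}"
            ds.columns.append(name)
            for row in ds.rows:
                row.append("1")
    if DefectItem.INACCURATE_FORMAT in spec.items:
        ds.columns.append(ds.columns[0])
        for row in ds.rows:
            row.append(row[0])
        ds.parse_flags.add(ParseFlag.DUPLICATE_COLUMN_NAMES)
    if DefectItem.UNANALYZABLE_STRUCTURE in spec.items:
        ds.parse_flags.add(ParseFlag.REPEATED_HEADER_ROWS)
    if DefectItem.MISSING_CODEBOOK in spec.items:
        sub.codebook = None

    return sub, frozenset(spec.items)


# ---------------------------------------------------------------------------
# Fixture reconstruction
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Marginal targets a generated submission collection must reproduce.

    ``band_counts`` maps zero/one/two-plus to dataset counts; stratifier
    margins map each level to its (not defective, defective) pair.  All
    margins must be jointly consistent with the band counts (zero-defect
    count = not-defective count).
    """

    phase: Phase
    band_counts: dict[DefectBand, int]
    total_defects: int
    capture_margins: dict[Capture, tuple[int, int]]
    coordinator_margins: dict[bool, tuple[int, int]]
    returning_margins: dict[bool, tuple[int, int]]
    missing_codebook_count: int = 0
    electronic_count: int = 0
    n_rows: int = 10

    @property
    def n(self) -> int:
        return sum(self.band_counts.values())

    def validate(self) -> None:
        n = self.n
        zero = self.band_counts.get(DefectBand.ZERO, 0)
        one = self.band_counts.get(DefectBand.ONE, 0)
        two = self.band_counts.get(DefectBand.TWO_PLUS, 0)
        minimum = one + 2 * two
        if self.total_defects < minimum:
            raise ValueError(
                f"infeasible fixture: total_defects={self.total_defects} below "
                f"the minimum {minimum} implied by band counts"
            )
        n_def = n - zero
        for name, margins in (
            ("capture", self.capture_margins),
            ("coordinator", self.coordinator_margins),
            ("returning_pi", self.returning_margins),
        ):
            nd = sum(v[0] for v in margins.values())
            df = sum(v[1] for v in margins.values())
            if (nd, df) != (zero, n_def):
                raise ValueError(
                    f"infeasible fixture: {name} margins sum to ({nd},{df}), "
                    f"expected ({zero},{n_def})"
                )
        if self.missing_codebook_count > n_def:
            raise ValueError(
                "infeasible fixture: more missing-codebook datasets than defective datasets"
            )


#: Baseline audit collection: 45 manually entered submissions, 105 defects.
PAPER_PRE_SPEC = FixtureSpec(
    phase=Phase.PRE,
    band_counts={DefectBand.ZERO: 6, DefectBand.ONE: 8, DefectBand.TWO_PLUS: 31},
    total_defects=105,
    capture_margins={Capture.SINGLE: (6, 15), Capture.MULTI: (0, 24)},
    coordinator_margins={False: (5, 23), True: (1, 16)},
    returning_margins={True: (3, 7), False: (3, 32)},
    missing_codebook_count=20,
    electronic_count=0,
)

#: Follow-up audit collection: 21 submissions, 12 defects.
PAPER_POST_SPEC = FixtureSpec(
    phase=Phase.POST,
    band_counts={DefectBand.ZERO: 17, DefectBand.ONE: 2, DefectBand.TWO_PLUS: 2},
    total_defects=12,
    capture_margins={Capture.SINGLE: (8, 4), Capture.MULTI: (9, 0)},
    coordinator_margins={False: (7, 4), True: (10, 0)},
    returning_margins={True: (14, 0), False: (3, 4)},
    missing_codebook_count=0,
    electronic_count=11,
)

# item pools for assigning identities to allocated defect counts; the
# codebook-less pool holds the only items observable without a codebook
_NO_CODEBOOK_POOL = [
    DefectItem.MISSING_CODEBOOK,
    DefectItem.INACCURATE_FORMAT,
    DefectItem.UNANALYZABLE_STRUCTURE,
    DefectItem.MISSING_ANALYTIC_VARS,
    DefectItem.MISSING_OUTCOME_VARS,
]
_WITH_CODEBOOK_POOL = [
    DefectItem.MISSING_VALUES,
    DefectItem.UNCODED_VALUES,
    DefectItem.EMBEDDED_VALUES,
    DefectItem.CODEBOOK_INCONSISTENCY,
    DefectItem.MISCODED_VALUES,
    DefectItem.IMPLAUSIBLE_VALUES,
    DefectItem.UNFORMATTED_VALUES,
    DefectItem.INACCURATE_FORMAT,
    DefectItem.UNANALYZABLE_STRUCTURE,
    DefectItem.MISSING_ANALYTIC_VARS,
    DefectItem.MISSING_OUTCOME_VARS,
]


def _allocate_scores(fspec: FixtureSpec) -> list[int]:
    """Per-dataset defect counts: zero band, one band, then two-plus with
    extra defects spread round-robin."""
    zero = fspec.band_counts.get(DefectBand.ZERO, 0)
    one = fspec.band_counts.get(DefectBand.ONE, 0)
    two = fspec.band_counts.get(DefectBand.TWO_PLUS, 0)
    scores = [0] * zero + [1] * one + [2] * two
    extra = fspec.total_defects - one - 2 * two
    i = 0
    while extra > 0 and two > 0:
        idx = zero + one + (i % two)
        if scores[idx] < 12:
            scores[idx] += 1
            extra -= 1
        i += 1
    return scores


def _assign_levels(
    margins_nondef: list[tuple[object, int]], margins_def: list[tuple[object, int]],
    scores: list[int],
) -> list[object]:
    """Deterministically hand out stratifier levels: within the
    non-defective group then the defective group, in margin order."""
    out: list[object] = []
    nd_iter = [lvl for lvl, cnt in margins_nondef for _ in range(cnt)]
    df_iter = [lvl for lvl, cnt in margins_def for _ in range(cnt)]
    i_nd = i_df = 0
    for s in scores:
        if s == 0:
            out.append(nd_iter[i_nd])
            i_nd += 1
        else:
            out.append(df_iter[i_df])
            i_df += 1
    return out


def build_fixture(
    fspec: FixtureSpec, seed: int = 0
) -> list[tuple[StudySubmission, frozenset[DefectItem]]]:
    """Build a submission collection reproducing the fixture targets exactly.

    Returns (submission, injected truth set) pairs.  Auditing the
    submissions yields band counts, total defects, missing-codebook count
    and every stratifier cross-tab equal to the spec's targets.
    """
    fspec.validate()
    scores = _allocate_scores(fspec)
    n = fspec.n

    def split(margins: dict) -> tuple[list, list]:
        return (
            [(lvl, v[0]) for lvl, v in margins.items()],
            [(lvl, v[1]) for lvl, v in margins.items()],
        )

    capture = _assign_levels(*split(fspec.capture_margins), scores)
    coordinator = _assign_levels(*split(fspec.coordinator_margins), scores)
    returning = _assign_levels(*split(fspec.returning_margins), scores)

    # missing codebook goes to the first datasets of the defective block
    codebookless: set[int] = set()
    remaining = fspec.missing_codebook_count
    for i, s in enumerate(scores):
        if remaining == 0:
            break
        if s > 0:
            if s > len(_NO_CODEBOOK_POOL):
                continue  # too many defects to express without a codebook
            codebookless.add(i)
            remaining -= 1
    if remaining:
        raise ValueError(
            "infeasible fixture: cannot place all missing-codebook datasets "
            "(defective datasets carry too many defects to express without a codebook)"
        )

    out: list[tuple[StudySubmission, frozenset[DefectItem]]] = []
    rotation = 0
    for i, s in enumerate(scores):
        cfg = GeneratorConfig(
            n_rows=fspec.n_rows,
            capture=capture[i],
            seed=_child_seed(seed, i),
            phase=fspec.phase,
            coordinator_on_board=bool(coordinator[i]),
            returning_pi=bool(returning[i]),
            entry_mode=EntryMode.ELECTRONIC if i < fspec.electronic_count else EntryMode.MANUAL,
            submission_id=f"{fspec.phase.value}-{i + 1:03d}",
        )
        sub = generate_clean(cfg)
        if s == 0:
            out.append((sub, frozenset()))
            continue
        if i in codebookless:
            items = frozenset(_NO_CODEBOOK_POOL[:s])
        else:
            pool = _WITH_CODEBOOK_POOL[rotation % 7 :] + _WITH_CODEBOOK_POOL[: rotation % 7]
            items = frozenset(pool[:s])
            rotation += 1
        mutated, truth = inject_defects(
            sub, InjectionSpec(items=items, seed=_child_seed(seed, n + i))
        )
        out.append((mutated, truth))
    return out


# ---------------------------------------------------------------------------
# Bundle I/O: one directory per submission
# ---------------------------------------------------------------------------

def write_bundle(
    submission: StudySubmission,
    directory: Union[str, Path],
    truth: Optional[frozenset[DefectItem]] = None,
) -> None:
    """Write a submission as ``dataset.csv`` + ``codebook.json`` +
    ``plan.json`` + ``meta.json`` (+ ``truth.json`` when labels are known)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_dataset(submission.dataset, d / "dataset.csv")
    if submission.codebook is not None:
        write_codebook(submission.codebook, d / "codebook.json")
    write_plan(submission.plan, d / "plan.json")
    write_meta(submission.meta, d / "meta.json")
    if truth is not None:
        with (d / "truth.json").open("w", encoding="utf-8") as fh:
            json.dump(sorted(i.value for i in truth), fh, indent=2)
            fh.write("\n")


def read_bundle(directory: Union[str, Path]) -> StudySubmission:
    d = Path(directory)
    codebook = d / "codebook.json"
    return read_submission(
        dataset_path=d / "dataset.csv",
        plan_path=d / "plan.json",
        meta=d / "meta.json",
        codebook_path=codebook if codebook.exists() else None,
        submission_id=d.name,
    )


def read_truth(directory: Union[str, Path]) -> Optional[frozenset[DefectItem]]:
    path = Path(directory) / "truth.json"
    if not path.exists():
        return None
    with path.open(encoding="utf-8") as fh:
        return frozenset(DefectItem(v) for v in json.load(fh))


def write_fixture(
    fixture: Sequence[tuple[StudySubmission, frozenset[DefectItem]]],
    out_dir: Union[str, Path],
) -> None:
    out = Path(out_dir)
    for sub, truth in fixture:
        write_bundle(sub, out / sub.submission_id, truth=truth)
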