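"""Categorical tests and the pre/post-intervention comparison report.

The inferential layer is deliberately small: Fisher's exact test on 2x2
defective-vs-stratifier tables (study design, coordinator on board,
returning investigator) and a Pearson chi-square test on the 3x2
defect-band x phase table.  The two-sided Fisher p-value follows the
point-probability convention — sum the hypergeometric probabilities of all
tables with the observed margins that are no more likely than the observed
one (ties judged at relative tolerance ~1e-7).  The chi-square test applies
no Yates continuity correction; a warning (not an error) is emitted when an
expected count falls below 5, since small audit collections routinely do.
Significance is reported against alpha = 0.05.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats as sps

from .checks import DefectProfile
from .conformance import DefectBand, band, is_defective
from .model import Capture, Phase

__all__ = [
    "ALPHA",
    "TestMethod",
    "ContingencyTable",
    "TestResult",
    "ComparisonReport",
    "fisher_exact_2x2",
    "chi_square_test",
    "pre_post_compare",
]

ALPHA = 0.05


class TestMethod(str, enum.Enum):
    FISHER = "fisher-exact"
    CHI_SQUARE = "chi-square"


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        r, c = self.counts.shape
        if r < 2 or c < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (r, c) != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match the counts shape")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("contingency table must have a positive grand total")

    def to_dict(self) -> dict:
        return {
            "row_labels": self.row_labels,
            "col_labels": self.col_labels,
            "counts": self.counts.tolist(),
        }


@dataclass
class TestResult:
    method: TestMethod
    p_value: float
    statistic: Optional[float] = None
    df: Optional[int] = None
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "method": self.method.value,
            "p_value": self.p_value,
            "statistic": self.statistic,
            "df": self.df,
            "alpha": self.alpha,
            "significant": self.significant,
        }


def fisher_exact_2x2(table: ContingencyTable) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    p is the sum of hypergeometric point probabilities, over all tables with
    the observed margins, that do not exceed the observed table's
    probability; clipped to [0, 1].
    """
    if table.counts.shape != (2, 2):
        raise ValueError(
            f"Fisher exact test requires a 2x2 table, got {table.counts.shape}"
        )
    p = float(sps.fisher_exact(table.counts, alternative="two-sided").pvalue)
    return TestResult(method=TestMethod.FISHER, p_value=min(max(p, 0.0), 1.0))


def chi_square_test(table: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a row or column margin is zero")
    expected = sps.contingency.expected_freq(counts)
    if (expected < 5).any():
        warnings.warn(
            "chi-square expected count below 5; the asymptotic p-value "
            "may be inaccurate",
            UserWarning,
            stacklevel=2,
        )
    res = sps.chi2_contingency(counts, correction=False)
    return TestResult(
        method=TestMethod.CHI_SQUARE,
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        df=int(res.dof),
    )


# ---------------------------------------------------------------------------
# Pre/post comparison
# ---------------------------------------------------------------------------

_BAND_ORDER = [DefectBand.ZERO, DefectBand.ONE, DefectBand.TWO_PLUS]


def _band_counts(profiles: Sequence[DefectProfile]) -> dict[DefectBand, int]:
    counts = {b: 0 for b in _BAND_ORDER}
    for p in profiles:
        counts[band(p)] += 1
    return counts


def _stratifier_table(
    profiles: Sequence[DefectProfile],
    levels: list[str],
    level_of,
) -> ContingencyTable:
    counts = np.zeros((2, 2), dtype=np.int64)
    for p in profiles:
        i = levels.index(level_of(p))
        counts[i, 1 if is_defective(p) else 0] += 1
    return ContingencyTable(
        row_labels=levels, col_labels=["not defective", "defective"], counts=counts
    )


_STRATIFIERS = {
    "capture": (
        [Capture.SINGLE.value, Capture.MULTI.value],
        lambda p: p.meta.capture.value,
    ),
    "coordinator": (["no", "yes"], lambda p: "yes" if p.meta.coordinator_on_board else "no"),
    "returning_pi": (["returning", "new"], lambda p: "returning" if p.meta.returning_pi else "new"),
}


@dataclass
class ComparisonReport:
    """Pre vs post comparison: band table + chi-square, per-phase Fisher
    tests on each stratifier, and per-phase band percentages (one decimal)."""

    band_table: ContingencyTable
    band_test: TestResult
    stratifier_tables: dict[str, ContingencyTable]
    stratifier_tests: dict[str, TestResult]
    proportions: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "band_table": self.band_table.to_dict(),
            "band_test": self.band_test.to_dict(),
            "stratifier_tables": {
                k: t.to_dict() for k, t in self.stratifier_tables.items()
            },
            "stratifier_tests": {
                k: t.to_dict() for k, t in self.stratifier_tests.items()
            },
            "proportions": self.proportions,
        }

    def write_json(self, path: Union[str, Path]) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def pre_post_compare(
    pre: Sequence[DefectProfile], post: Sequence[DefectProfile]
) -> ComparisonReport:
    """Compare defect distributions between the two phases.

    Builds the band x phase (3x2) table, tests it with Pearson chi-square,
    and runs Fisher's exact test on each 2x2 defective-vs-stratifier table
    within each phase.  A stratifier test is skipped (absent from the
    result) for a phase where its table has a zero grand total.
    """
    pre, post = list(pre), list(post)
    if not pre or not post:
        raise ValueError("both phases need at least one profile")

    pre_counts = _band_counts(pre)
    post_counts = _band_counts(post)
    band_table = ContingencyTable(
        row_labels=[b.value for b in _BAND_ORDER],
        col_labels=["pre", "post"],
        counts=np.array(
            [[pre_counts[b], post_counts[b]] for b in _BAND_ORDER], dtype=np.int64
        ),
    )
    band_test = chi_square_test(band_table)

    tables: dict[str, ContingencyTable] = {}
    tests: dict[str, TestResult] = {}
    for name, (levels, level_of) in _STRATIFIERS.items():
        for phase, profiles in ((Phase.PRE, pre), (Phase.POST, post)):
            key = f"{name}_{phase.value}"
            table = _stratifier_table(profiles, levels, level_of)
            tables[key] = table
            tests[key] = fisher_exact_2x2(table)

    proportions = {
        phase: {
            b.value: round(counts[b] / n * 100, 1) for b in _BAND_ORDER
        }
        for phase, counts, n in (
            ("pre", pre_counts, len(pre)),
            ("post", post_counts, len(post)),
        )
    }
    return ComparisonReport(
        band_table=band_table,
        band_test=band_test,
        stratifier_tables=tables,
        stratifier_tests=tests,
        proportions=proportions,
    )
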