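"""Conformance classification and defect-count banding.

Datasets with documentation or structural defects (missing codebook,
codebook inconsistencies, inaccurate format, unanalyzable structure, missing
outcome variables) are *unacceptable*: they cannot enter statistical
analysis until fixed.  Datasets with only cell-level entry errors (or a
missing analytic variable) are *sub-optimal*: analyzable after cleaning.
Zero-defect datasets are *conforming*.  Unacceptable takes precedence when
a submission carries defects of both groups.
"""

from __future__ import annotations

import enum

from .checks import DefectItem, DefectProfile

__all__ = [
    "ConformanceClass",
    "DefectBand",
    "UNACCEPTABLE_ITEMS",
    "SUB_OPTIMAL_ITEMS",
    "classify",
    "band",
    "is_defective",
]


class ConformanceClass(str, enum.Enum):
    UNACCEPTABLE = "unacceptable"
    SUB_OPTIMAL = "sub-optimal"
    CONFORMING = "conforming"


class DefectBand(str, enum.Enum):
    ZERO = "zero"
    ONE = "one"
    TWO_PLUS = "two-plus"


UNACCEPTABLE_ITEMS = frozenset(
    {
        DefectItem.MISSING_CODEBOOK,
        DefectItem.CODEBOOK_INCONSISTENCY,
        DefectItem.INACCURATE_FORMAT,
        DefectItem.UNANALYZABLE_STRUCTURE,
        DefectItem.MISSING_OUTCOME_VARS,
    }
)

SUB_OPTIMAL_ITEMS = frozenset(
    {
        DefectItem.UNCODED_VALUES,
        DefectItem.MISCODED_VALUES,
        DefectItem.MISSING_VALUES,
        DefectItem.IMPLAUSIBLE_VALUES,
        DefectItem.EMBEDDED_VALUES,
        DefectItem.UNFORMATTED_VALUES,
        DefectItem.MISSING_ANALYTIC_VARS,
    }
)


def classify(profile: DefectProfile) -> ConformanceClass:
    """Conformance class of a profile; unacceptable outranks sub-optimal."""
    if profile.present_items & UNACCEPTABLE_ITEMS:
        return ConformanceClass.UNACCEPTABLE
    if profile.present_items & SUB_OPTIMAL_ITEMS:
        return ConformanceClass.SUB_OPTIMAL
    return ConformanceClass.CONFORMING


def band(profile: DefectProfile) -> DefectBand:
    """Defect-count band: zero, one, or two-plus defects."""
    if profile.score == 0:
        return DefectBand.ZERO
    if profile.score == 1:
        return DefectBand.ONE
    return DefectBand.TWO_PLUS


def is_defective(profile: DefectProfile) -> bool:
    """True iff the submission carries at least one checklist defect."""
    return profile.score >= 1
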