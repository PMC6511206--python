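"""Audit-report assembly and rendering.

An :class:`AuditReport` ties together the per-submission defect profiles
(with conformance class and defect band) and the collection-level Six Sigma
metrics and Pareto table, plus an optional pre/post comparison.  Every
number in a report is produced by the library operations; this module only
arranges and serializes them, so a report's collection-level block is always
recomputable from its per-submission section.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .checks import CheckConfig, DEFAULT_CONFIG, DefectProfile, run_checklist
from .conformance import ConformanceClass, DefectBand, band, classify
from .metrics import MetricsSummary, ParetoTable, compute_metrics, pareto
from .model import StudySubmission
from .stats import ComparisonReport

__all__ = ["AuditReport", "audit_collection", "render_metrics_table", "render_comparison"]


@dataclass
class AuditReport:
    profiles: list[DefectProfile]
    classes: list[ConformanceClass]
    bands: list[DefectBand]
    metrics: MetricsSummary
    pareto: ParetoTable
    comparison: Optional[ComparisonReport] = None

    def per_submission_records(self) -> list[dict]:
        return [
            {
                "submission_id": p.submission_id,
                "score": p.score,
                "items": sorted(i.value for i in p.present_items),
                "conformance": c.value,
                "band": b.value,
            }
            for p, c, b in zip(self.profiles, self.classes, self.bands)
        ]

    def to_dict(self) -> dict:
        doc = {
            "submissions": self.per_submission_records(),
            "metrics": self.metrics.to_dict(),
            "pareto": self.pareto.to_records(),
        }
        if self.comparison is not None:
            doc["comparison"] = self.comparison.to_dict()
        return doc

    def write_json(self, path: Union[str, Path]) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def write_csv(self, path: Union[str, Path]) -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(
                fh, fieldnames=["submission_id", "score", "items", "conformance", "band"]
            )
            w.writeheader()
            for rec in self.per_submission_records():
                rec = dict(rec, items=";".join(rec["items"]))
                w.writerow(rec)


def audit_collection(
    submissions: Sequence[StudySubmission],
    config: CheckConfig = DEFAULT_CONFIG,
    opportunities_per_unit: int = 12,
) -> AuditReport:
    """Audit every submission and summarize the collection."""
    profiles = [run_checklist(s, config) for s in submissions]
    return AuditReport(
        profiles=profiles,
        classes=[classify(p) for p in profiles],
        bands=[band(p) for p in profiles],
        metrics=compute_metrics(profiles, opportunities_per_unit),
        pareto=pareto(profiles),
    )


def _render_rows(rows: list[list[str]]) -> str:
    widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
    lines = []
    for j, row in enumerate(rows):
        lines.append("  ".join(c.ljust(w) for c, w in zip(row, widths)).rstrip())
        if j == 0:
            lines.append("  ".join("-" * w for w in widths))
    return "\n".join(lines)


def render_metrics_table(summary: MetricsSummary) -> str:
    d = summary.display()
    rows = [
        ["measure", "value"],
        ["units inspected", str(summary.n_units)],
        ["opportunities/unit", str(summary.opportunities_per_unit)],
        ["total defects", str(summary.total_defects)],
        ["DPU", f"{d['dpu']:.2f}"],
        ["DPMO", f"{d['dpmo']:,.2f}"],
        ["Yield (%)", f"{d['yield_pct']:.2f}"],
        ["Sigma", f"{d['sigma']:.1f}"],
    ]
    return _render_rows(rows)


def render_comparison(
    pre_metrics: MetricsSummary,
    post_metrics: MetricsSummary,
    comparison: ComparisonReport,
) -> str:
    """Aligned-text summary: defect bands and sigma metrics per phase."""
    dp, dq = pre_metrics.display(), post_metrics.display()
    bt = comparison.band_table
    rows = [["measure", "pre", "post"]]
    for i, label in enumerate(bt.row_labels):
        pre_n, post_n = bt.counts[i]
        rows.append(
            [
                f"{label} defects",
                f"{pre_n} ({comparison.proportions['pre'][label]})",
                f"{post_n} ({comparison.proportions['post'][label]})",
            ]
        )
    rows += [
        ["DPU", f"{dp['dpu']:.2f}", f"{dq['dpu']:.2f}"],
        ["DPMO", f"{dp['dpmo']:,.2f}", f"{dq['dpmo']:,.2f}"],
        ["Yield", f"{dp['yield_pct']:.2f}", f"{dq['yield_pct']:.2f}"],
        ["SIGMA", f"{dp['sigma']:.1f}", f"{dq['sigma']:.1f}"],
    ]
    text = _render_rows(rows)
    test = comparison.band_test
    text += (
        f"\n\nband-shift chi-square: statistic={test.statistic:.2f}, "
        f"df={test.df}, p={'<0.001' if test.p_value < 0.001 else format(test.p_value, '.3f')}"
    )
    return text
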