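"""Six Sigma data-quality metrics and Pareto analysis over audit profiles.

Each audited dataset is one *unit*; each checklist item is one defect
*opportunity*, so a unit has 12 opportunities by default.  From the total
defect count D over n units with o opportunities each:

    DPU   = D / n                      (defects per unit)
    DPO   = D / (n * o)                (defects per opportunity)
    DPMO  = DPO * 1e6                  (defects per million opportunities)
    Yield = (1 - DPO) * 100            (% of opportunities that conform)
    Sigma = Phi^-1(1 - DPO) + 1.5      (process sigma, conventional
                                        1.5-sigma long-term shift; six sigma
                                        corresponds to 3.4 DPMO)

Internally everything is kept at full precision.  For display, DPU, DPMO
and Yield are *truncated* (not rounded) to two decimals and Sigma is rounded
to one — the truncation convention is deliberate: it is the one that
reproduces conventional printed tables of these quantities exactly
(e.g. 105/540 -> DPMO 194,444.44, Yield 80.55 rather than 80.56).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

from scipy.stats import norm

from .checks import DefectItem, DefectProfile
from .conformance import DefectBand, band

__all__ = [
    "MetricsSummary",
    "ParetoRow",
    "ParetoTable",
    "compute_metrics",
    "pareto",
    "truncate",
    "plot_pareto",
]


def truncate(x: float, decimals: int = 2) -> float:
    """Truncate (chop) a non-negative value to a fixed number of decimals."""
    if math.isinf(x) or math.isnan(x):
        return x
    scale = 10**decimals
    return math.floor(x * scale) / scale


@dataclass
class MetricsSummary:
    """Six Sigma summary of a profile collection (full-precision fields)."""

    n_units: int
    opportunities_per_unit: int
    total_defects: int
    dpu: float
    dpo: float
    dpmo: float
    yield_pct: float
    sigma_level: float
    band_counts: dict[DefectBand, int]

    def display(self) -> dict[str, float]:
        """Values on the conventional reporting scale: DPU/DPMO/Yield
        truncated to two decimals, Sigma rounded to one."""
        return {
            "dpu": truncate(self.dpu, 2),
            "dpo": truncate(self.dpo, 4),
            "dpmo": truncate(self.dpmo, 2),
            "yield_pct": truncate(self.yield_pct, 2),
            "sigma": self.sigma_level
            if math.isinf(self.sigma_level)
            else round(self.sigma_level, 1),
        }

    def to_dict(self) -> dict:
        d = {
            "n_units": self.n_units,
            "opportunities_per_unit": self.opportunities_per_unit,
            "total_defects": self.total_defects,
            "dpu": self.dpu,
            "dpo": self.dpo,
            "dpmo": self.dpmo,
            "yield_pct": self.yield_pct,
            "sigma_level": self.sigma_level,
            "band_counts": {b.value: c for b, c in self.band_counts.items()},
            "display": self.display(),
        }
        return d


def compute_metrics(
    profiles: Sequence[DefectProfile], opportunities_per_unit: int = 12
) -> MetricsSummary:
    """Compute DPU/DPO/DPMO/Yield/Sigma over a collection of audit profiles."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("compute_metrics requires a non-empty profile collection")
    if opportunities_per_unit < 1:
        raise ValueError("opportunities_per_unit must be a positive integer")
    max_score = max(p.score for p in profiles)
    if opportunities_per_unit < max_score:
        raise ValueError(
            f"opportunities_per_unit={opportunities_per_unit} is below the "
            f"maximum observed score {max_score}: impossible configuration"
        )
    n = len(profiles)
    total = sum(p.score for p in profiles)
    dpu = total / n
    dpo = total / (n * opportunities_per_unit)
    dpmo = dpo * 1_000_000
    yield_pct = (1 - dpo) * 100
    sigma = float(norm.ppf(1 - dpo)) + 1.5

    counts = {b: 0 for b in DefectBand}
    for p in profiles:
        counts[band(p)] += 1
    return MetricsSummary(
        n_units=n,
        opportunities_per_unit=opportunities_per_unit,
        total_defects=total,
        dpu=dpu,
        dpo=dpo,
        dpmo=dpmo,
        yield_pct=yield_pct,
        sigma_level=sigma,
        band_counts=counts,
    )


@dataclass
class ParetoRow:
    item: DefectItem
    affected_dataset_count: int
    pct_of_datasets: float
    cumulative_pct_of_defects: float


@dataclass
class ParetoTable:
    """Per-item dataset counts sorted descending, with cumulative shares.

    ``pct_of_datasets`` is count / n_units * 100.  The cumulative column is
    the running share of all defect occurrences (item presences), reaching
    100% at the last nonzero row.  Ties are broken by checklist order.
    """

    rows: list[ParetoRow]
    n_units: int

    def to_records(self) -> list[dict]:
        return [
            {
                "item": r.item.value,
                "affected_datasets": r.affected_dataset_count,
                "pct_of_datasets": r.pct_of_datasets,
                "cumulative_pct_of_defects": r.cumulative_pct_of_defects,
            }
            for r in self.rows
        ]

    def row_for(self, item: DefectItem) -> ParetoRow:
        for r in self.rows:
            if r.item is item:
                return r
        raise KeyError(item)


def pareto(profiles: Sequence[DefectProfile]) -> ParetoTable:
    """Rank checklist items by how many datasets exhibit them.

    Presence is binary per dataset (an item affecting 100 cells of one
    dataset counts once), so the counts sum to the total defect score.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("pareto requires a non-empty profile collection")
    n = len(profiles)
    counts = {item: 0 for item in DefectItem}
    for p in profiles:
        for item in p.present_items:
            counts[item] += 1
    ordered = sorted(DefectItem, key=lambda it: (-counts[it], it.order))
    total = sum(counts.values())
    rows: list[ParetoRow] = []
    cum = 0
    for item in ordered:
        cum += counts[item]
        rows.append(
            ParetoRow(
                item=item,
                affected_dataset_count=counts[item],
                pct_of_datasets=counts[item] / n * 100,
                cumulative_pct_of_defects=(cum / total * 100) if total else 0.0,
            )
        )
    return ParetoTable(rows=rows, n_units=n)


def write_pareto_csv(table: ParetoTable, path: Union[str, Path]) -> None:
    import csv

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(
            fh,
            fieldnames=[
                "item",
                "affected_datasets",
                "pct_of_datasets",
                "cumulative_pct_of_defects",
            ],
        )
        w.writeheader()
        for rec in table.to_records():
            w.writerow(rec)


def write_metrics_json(summary: MetricsSummary, path: Union[str, Path]) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
        fh.write("\n")


def plot_pareto(table: ParetoTable, path: Union[str, Path]) -> None:
    """Bar + cumulative-line Pareto chart (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nonzero = [r for r in table.rows if r.affected_dataset_count > 0] or table.rows
    labels = [r.item.value for r in nonzero]
    counts = [r.affected_dataset_count for r in nonzero]
    cum = [r.cumulative_pct_of_defects for r in nonzero]

    fig, ax1 = plt.subplots(figsize=(9, 4.5))
    ax1.bar(range(len(labels)), counts, color="#4878b0")
    ax1.set_xticks(range(len(labels)))
    ax1.set_xticklabels(labels, rotation=40, ha="right", fontsize=8)
    ax1.set_ylabel("datasets affected")
    ax2 = ax1.twinx()
    ax2.plot(range(len(labels)), cum, "o-", color="#c44e52")
    ax2.set_ylabel("cumulative % of defects")
    ax2.set_ylim(0, 105)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
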