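"""Stringent candidate-DMR gates and shortlist/scatter reporting.

A differentially methylated region on an imprinted locus is methylated on
one parental allele and not the other, so in bulk bisulfite data its CGI
sits near 50% methylation with a *low* spread across CpG sites (every site
is half-methylated), on top of adequate coverage and CpG content.  The
default gates encode that signature:

* overall methylation between 45 and 55% (inclusive),
* population SD of per-site methylation below 25% (strict),
* more than 400 sequencing read observations (strict),
* more than 95 covered CpG sites (strict),
* CpG density above 4% (strict).

Every threshold is a config field so the screen can be re-tuned for other
species or sequencing depths.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from .association import CGIAnnotation
from .summarize import CGIMethylationSummary, UncoveredIslandError, classify

GATE_NAMES = ("methylation", "std", "reads", "sites", "density")


@dataclass(frozen=True)
class FilterCriteria:
    meth_min_pct: float = 45.0
    meth_max_pct: float = 55.0
    std_max_pct: float = 25.0
    min_reads: int = 400
    min_sites: int = 95
    min_density_pct: float = 4.0
    basis: str = "mean"  # which percent the methylation gate reads

    def __post_init__(self) -> None:
        if self.meth_min_pct >= self.meth_max_pct:
            raise ValueError("meth_min_pct must be below meth_max_pct")
        for name in ("meth_min_pct", "std_max_pct", "min_reads",
                     "min_sites", "min_density_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FilterCriteria":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class DMRCandidate:
    summary: CGIMethylationSummary
    gate_results: dict
    is_candidate: bool


def apply_gates(
    summary: CGIMethylationSummary, criteria: FilterCriteria = FilterCriteria()
) -> DMRCandidate:
    """Evaluate the five gates on one covered summary.

    The methylation-range gate is inclusive at both ends; the spread gate
    is strict below; the reads, sites and density gates are strict above.
    The sites gate counts *covered* CpG sites (uncovered sites contribute
    nothing to the statistics the gates protect).
    """
    if not summary.covered:
        raise UncoveredIslandError(
            f"island {summary.island.name} has no covered CpG sites"
        )
    pct = summary.percent(criteria.basis)
    gates = {
        "methylation": criteria.meth_min_pct <= pct <= criteria.meth_max_pct,
        "std": summary.std_pct < criteria.std_max_pct,
        "reads": summary.total_reads > criteria.min_reads,
        "sites": summary.n_sites_covered > criteria.min_sites,
        "density": summary.island.density_pct > criteria.min_density_pct,
    }
    return DMRCandidate(summary, gates, all(gates.values()))


def _summary_row(s: CGIMethylationSummary, criteria: FilterCriteria) -> dict:
    return {
        "island": s.island.name,
        "contig": s.island.interval.contig_id,
        "start": s.island.interval.start,
        "end": s.island.interval.end,
        "n_cpg": s.island.n_cpg,
        "density_pct": s.island.density_pct,
        "mean_pct": s.mean_pct,
        "weighted_pct": s.weighted_pct,
        "std_pct": s.std_pct,
        "total_reads": s.total_reads,
        "n_sites_covered": s.n_sites_covered,
        "class": classify(s, criteria.basis) if s.covered else "uncovered",
    }


def shortlist(
    candidates: list[DMRCandidate],
    annotations: list[CGIAnnotation] | None = None,
    criteria: FilterCriteria = FilterCriteria(),
) -> pd.DataFrame:
    """Candidate table joined to gene annotations, ordered for triage.

    Rows are sorted by distance of the methylation percent from 50 (closest
    first), ties broken by total reads descending.  A candidate with no
    associated feature keeps one row with an empty feature field (outer
    join), so the row count is sum over candidates of max(1, n annotations).
    """
    ann_by_island: dict[str, list[CGIAnnotation]] = {}
    for a in annotations or []:
        ann_by_island.setdefault(a.island.name, []).append(a)
    rows = []
    for c in candidates:
        if not c.is_candidate:
            continue
        base = _summary_row(c.summary, criteria)
        anns = ann_by_island.get(c.summary.island.name, [])
        if not anns:
            rows.append({**base, "feature_id": "", "relation": "", "distance_bp": -1})
        for a in anns:
            rows.append(
                {
                    **base,
                    "feature_id": a.feature_id,
                    "relation": a.relation,
                    "distance_bp": a.distance_bp,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "island", "contig", "start", "end", "n_cpg", "density_pct",
            "mean_pct", "weighted_pct", "std_pct", "total_reads",
            "n_sites_covered", "class", "feature_id", "relation", "distance_bp",
        ],
    )
    if df.empty:
        return df
    df["_dist50"] = (df["mean_pct"] - 50.0).abs()
    df = df.sort_values(
        ["_dist50", "total_reads"], ascending=[True, False], kind="mergesort"
    ).drop(columns="_dist50")
    return df.reset_index(drop=True)


def scatter_data(
    summaries: list[CGIMethylationSummary],
    criteria: FilterCriteria = FilterCriteria(),
) -> pd.DataFrame:
    """One row per covered CGI: (mean_pct, std_pct, class, is_candidate).

    This is the data behind the percent-methylation vs. cross-site-SD
    scatter on which the candidate gate box is drawn.
    """
    rows = []
    for s in summaries:
        if not s.covered:
            continue
        rows.append(
            {
                "island": s.island.name,
                "mean_pct": s.mean_pct,
                "weighted_pct": s.weighted_pct,
                "std_pct": s.std_pct,
                "class": classify(s, criteria.basis),
                "is_candidate": apply_gates(s, criteria).is_candidate,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["island", "mean_pct", "weighted_pct", "std_pct", "class",
                 "is_candidate"],
    )
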