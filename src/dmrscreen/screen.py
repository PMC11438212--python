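"""End-to-end candidate-DMR screen: detect -> summarize -> associate -> filter."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .association import CGIAnnotation, associate, association_table
from .cgi import (
    DEFAULT_MIN_DENSITY_PCT,
    DEFAULT_TILE_BP,
    CpGIsland,
    detect_cgis,
)
from .core import CpGSiteMethylation, DmrScreenError, GeneFeature, GenomeSequence
from .filtering import DMRCandidate, FilterCriteria, apply_gates, scatter_data, shortlist
from .summarize import CGIMethylationSummary, summarize_islands

logger = logging.getLogger("dmrscreen")


class ContigMismatchError(DmrScreenError):
    pass


@dataclass
class ScreenResult:
    islands: list[CpGIsland]
    summaries: list[CGIMethylationSummary]
    annotations: list[CGIAnnotation]
    candidates: list[DMRCandidate]
    summary_table: pd.DataFrame = field(repr=False)
    candidate_table: pd.DataFrame = field(repr=False)
    scatter_table: pd.DataFrame = field(repr=False)
    association_report: pd.DataFrame = field(repr=False)

    @property
    def stage_counts(self) -> dict[str, int]:
        return {
            "cgis_detected": len(self.islands),
            "cgis_covered": sum(1 for s in self.summaries if s.covered),
            "candidates": sum(1 for c in self.candidates if c.is_candidate),
        }


def validate_contig_names(
    genomes: list[GenomeSequence],
    features: list[GeneFeature],
    sites: list[CpGSiteMethylation],
) -> None:
    """Hard error listing contig names absent from the genome FASTA."""
    known = {g.contig_id for g in genomes}
    bad_features = sorted({f.interval.contig_id for f in features} - known)
    bad_sites = sorted({s.contig_id for s in sites} - known)
    if bad_features or bad_sites:
        parts = []
        if bad_features:
            parts.append(f"annotation contigs not in genome: {bad_features}")
        if bad_sites:
            parts.append(f"coverage contigs not in genome: {bad_sites}")
        raise ContigMismatchError("; ".join(parts))


def run_screen(
    genomes: list[GenomeSequence],
    features: list[GeneFeature],
    sites: list[CpGSiteMethylation],
    criteria: FilterCriteria = FilterCriteria(),
    tile_bp: int = DEFAULT_TILE_BP,
    min_density_pct: float = DEFAULT_MIN_DENSITY_PCT,
    density_multiplier: int = 1,
    flank_bp: int = 5000,
) -> ScreenResult:
    """Run the full screen over in-memory inputs."""
    validate_contig_names(genomes, features, sites)

    islands: list[CpGIsland] = []
    for g in genomes:
        islands.extend(
            detect_cgis(g, tile_bp=tile_bp, min_density_pct=min_density_pct,
                        density_multiplier=density_multiplier)
        )
    logger.info("detected %d CpG islands", len(islands))

    summaries = summarize_islands(islands, sites)
    covered = [s for s in summaries if s.covered]
    logger.info("%d of %d islands have methylation coverage",
                len(covered), len(islands))

    annotations = associate(islands, features, flank_bp=flank_bp)
    logger.info("%d island-feature annotations", len(annotations))

    candidates = [apply_gates(s, criteria) for s in covered]
    n_cand = sum(1 for c in candidates if c.is_candidate)
    logger.info("%d candidate DMRs pass all gates", n_cand)

    from .filtering import _summary_row  # tabular form shared with shortlist

    summary_table = pd.DataFrame(
        [_summary_row(s, criteria) if s.covered else
         {**_summary_row_uncovered(s)} for s in summaries]
    )
    return ScreenResult(
        islands=islands,
        summaries=summaries,
        annotations=annotations,
        candidates=candidates,
        summary_table=summary_table,
        candidate_table=shortlist(candidates, annotations, criteria),
        scatter_table=scatter_data(covered, criteria),
        association_report=association_table(islands, annotations),
    )


def _summary_row_uncovered(s: CGIMethylationSummary) -> dict:
    return {
        "island": s.island.name,
        "contig": s.island.interval.contig_id,
        "start": s.island.interval.start,
        "end": s.island.interval.end,
        "n_cpg": s.island.n_cpg,
        "density_pct": s.island.density_pct,
        "mean_pct": float("nan"),
        "weighted_pct": float("nan"),
        "std_pct": float("nan"),
        "total_reads": 0,
        "n_sites_covered": 0,
        "class": "uncovered",
    }
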