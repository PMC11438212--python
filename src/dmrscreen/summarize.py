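"""Per-CGI methylation summaries from per-CpG bisulfite coverage.

Coverage is mapped onto each island by genomic location and averaged over
the covered CpG sites within it.  Two percent-methylation estimates are
kept side by side: the unweighted mean of per-site percents (the default
basis downstream) and the read-weighted percent
``100 * sum(meth) / sum(meth + unmeth)``.  The spread statistic is the
population standard deviation of the per-site percents, which for values
bounded in [0, 100] cannot exceed 50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cgi import CpGIsland
from .core import CpGSiteMethylation, DmrScreenError, GenomeSequence

HIGH_METH_PCT = 80.0
LOW_METH_PCT = 20.0

CLASS_HIGH = "highly_methylated"
CLASS_LOW = "highly_unmethylated"
CLASS_MID = "intermediate"


class UncoveredIslandError(DmrScreenError):
    """Raised when a statistic is requested for an island with no coverage."""


@dataclass(frozen=True)
class CGIMethylationSummary:
    island: CpGIsland
    mean_pct: float  # nan when uncovered
    weighted_pct: float
    std_pct: float
    total_reads: int
    n_sites_covered: int

    @property
    def covered(self) -> bool:
        return self.n_sites_covered > 0

    def percent(self, basis: str = "mean") -> float:
        if basis == "mean":
            return self.mean_pct
        if basis == "weighted":
            return self.weighted_pct
        raise ValueError(f"unknown basis {basis!r}")


def summarize_cgi(
    island: CpGIsland, sites: list[CpGSiteMethylation]
) -> CGIMethylationSummary:
    """Summarize the covered CpG sites falling inside one island.

    Sites outside the island interval or on other contigs are ignored.
    An island with no covered site is flagged uncovered (statistics NaN),
    never raised.
    """
    iv = island.interval
    percents = []
    meth = unmeth = 0
    for s in sites:
        if s.contig_id != iv.contig_id or not iv.contains(s.pos):
            continue
        if s.coverage == 0:
            continue
        percents.append(s.percent)
        meth += s.count_meth
        unmeth += s.count_unmeth
    n = len(percents)
    if n == 0:
        return CGIMethylationSummary(island, math.nan, math.nan, math.nan, 0, 0)
    # sorted reduction makes the floating-point result order-invariant
    arr = np.sort(np.asarray(percents, dtype=float))
    return CGIMethylationSummary(
        island=island,
        mean_pct=float(arr.mean()),
        weighted_pct=100.0 * meth / (meth + unmeth),
        std_pct=float(arr.std(ddof=0)),
        total_reads=meth + unmeth,
        n_sites_covered=n,
    )


def summarize_islands(
    islands: list[CpGIsland], sites: list[CpGSiteMethylation]
) -> list[CGIMethylationSummary]:
    """Vectorized summary of many islands against one site list."""
    by_contig: dict[str, list[CpGSiteMethylation]] = {}
    for s in sites:
        if s.coverage > 0:
            by_contig.setdefault(s.contig_id, []).append(s)
    index: dict[str, tuple[np.ndarray, list[CpGSiteMethylation]]] = {}
    for contig, ss in by_contig.items():
        ss.sort(key=lambda s: s.pos)
        index[contig] = (np.array([s.pos for s in ss], dtype=np.int64), ss)

    out = []
    for isl in islands:
        entry = index.get(isl.interval.contig_id)
        if entry is None:
            out.append(summarize_cgi(isl, []))
            continue
        pos, ss = entry
        lo = int(np.searchsorted(pos, isl.interval.start, side="left"))
        hi = int(np.searchsorted(pos, isl.interval.end, side="left"))
        out.append(summarize_cgi(isl, ss[lo:hi]))
    return out


def classify(summary: CGIMethylationSummary, basis: str = "mean") -> str:
    """Label a covered summary as highly methylated / unmethylated / intermediate.

    Strict thresholds: above 80% is highly methylated, below 20% highly
    unmethylated, exactly 80 or 20 is intermediate.
    """
    if not summary.covered:
        raise UncoveredIslandError(
            f"island {summary.island.name} has no covered CpG sites"
        )
    pct = summary.percent(basis)
    if pct > HIGH_METH_PCT:
        return CLASS_HIGH
    if pct < LOW_METH_PCT:
        return CLASS_LOW
    return CLASS_MID


def collapse_strands(
    sites: list[CpGSiteMethylation], genomes: list[GenomeSequence]
) -> list[CpGSiteMethylation]:
    """Fold strand-resolved records onto the forward-strand C of each CpG.

    Some extractors emit separate top-strand (position of the C) and
    bottom-strand (position of the G, one base right) records for the same
    biological CpG.  Given the genome, any record sitting on the G of a CpG
    is merged into the record keyed by the C; other records pass through.
    """
    seq_by_id = {g.contig_id: g.sequence for g in genomes}
    merged: dict[tuple[str, int], list[int]] = {}
    order: list[tuple[str, int]] = []
    for s in sites:
        seq = seq_by_id.get(s.contig_id)
        pos = s.pos
        if (
            seq is not None
            and pos >= 1
            and seq[pos - 1 : pos + 1] == "CG"
        ):
            pos = pos - 1  # bottom-strand record -> forward-strand C
        key = (s.contig_id, pos)
        if key not in merged:
            merged[key] = [0, 0]
            order.append(key)
        merged[key][0] += s.count_meth
        merged[key][1] += s.count_unmeth
    return [
        CpGSiteMethylation(c, p, m, u) for (c, p), (m, u) in
        ((k, merged[k]) for k in order)
    ]
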