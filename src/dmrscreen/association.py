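"""Associate CpG islands with gene features by positional relation.

Six relations are recognised for an (island, feature) pair on the same
contig: the island lying within the feature, starting inside it, ending
inside it, spanning it entirely, lying within a flank (default 5 kb) of the
feature start site, or within the same flank downstream of the feature end.
"start" and "downstream of the end" are strand-aware by default: the start
site is the 5' end of the feature on its own strand.

When several relations hold simultaneously exactly one is reported per
pair, with overlap relations taking precedence over flank relations:
within > spans > starts_inside > ends_inside > near_start > near_end.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cgi import CpGIsland
from .core import GeneFeature, GenomicInterval

WITHIN = "within_feature"
STARTS_INSIDE = "starts_inside"
ENDS_INSIDE = "ends_inside"
SPANS = "spans_feature"
NEAR_START = "near_start"
NEAR_END = "near_end"

RELATION_PRIORITY = (WITHIN, SPANS, STARTS_INSIDE, ENDS_INSIDE, NEAR_START, NEAR_END)

DEFAULT_FLANK_BP = 5000


@dataclass(frozen=True)
class CGIAnnotation:
    island: CpGIsland
    feature_id: str
    relation: str
    distance_bp: int  # 0 for overlap relations; gap size for near_* relations


def _pair_relations(
    iv: GenomicInterval,
    fv: GenomicInterval,
    flank_bp: int,
    strand_aware: bool,
) -> list[tuple[str, int]]:
    """All relations holding for one same-contig pair, with distances."""
    s, e = iv.start, iv.end
    fs, fe = fv.start, fv.end
    rels: list[tuple[str, int]] = []
    if s < fe and fs < e:  # overlap
        if s >= fs and e <= fe:
            rels.append((WITHIN, 0))
        if s <= fs and e >= fe:
            rels.append((SPANS, 0))
        if s >= fs and e > fe:
            rels.append((STARTS_INSIDE, 0))
        if s < fs and e <= fe:
            rels.append((ENDS_INSIDE, 0))
        return rels
    # no overlap: flank relations relative to the feature's 5'/3' ends
    minus = strand_aware and fv.strand == "-"
    # gap on the genomic left of the feature / right of the feature
    left_gap = fs - e if e <= fs else None
    right_gap = s - fe if s >= fe else None
    upstream_gap, downstream_gap = (
        (right_gap, left_gap) if minus else (left_gap, right_gap)
    )
    if upstream_gap is not None and upstream_gap <= flank_bp:
        rels.append((NEAR_START, upstream_gap))
    if downstream_gap is not None and downstream_gap <= flank_bp:
        rels.append((NEAR_END, downstream_gap))
    return rels


def associate(
    islands: list[CpGIsland],
    features: list[GeneFeature],
    flank_bp: int = DEFAULT_FLANK_BP,
    strand_aware: bool = True,
    all_relations: bool = False,
) -> list[CGIAnnotation]:
    """Annotate every island against every same-contig feature.

    By default one relation (the highest-priority one) is reported per
    qualifying pair; ``all_relations=True`` reports every relation that
    holds.  Islands matching no feature yield no rows here; use
    :func:`association_table` for the report that also lists them.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    by_contig: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_contig.setdefault(f.interval.contig_id, []).append(f)

    out: list[CGIAnnotation] = []
    for isl in islands:
        for feat in by_contig.get(isl.interval.contig_id, []):
            rels = _pair_relations(
                isl.interval, feat.interval, flank_bp, strand_aware
            )
            if not rels:
                continue
            if all_relations:
                chosen = rels
            else:
                chosen = [min(rels, key=lambda r: RELATION_PRIORITY.index(r[0]))]
            for rel, dist in chosen:
                out.append(CGIAnnotation(isl, feat.feature_id, rel, dist))
    return out


def association_table(
    islands: list[CpGIsland], annotations: list[CGIAnnotation]
) -> pd.DataFrame:
    """Tabular report: one row per annotation, plus 'none' rows for islands
    with no associated feature."""
    annotated = {a.island.name for a in annotations}
    rows = [
        {
            "island": a.island.name,
            "feature_id": a.feature_id,
            "relation": a.relation,
            "distance_bp": a.distance_bp,
        }
        for a in annotations
    ]
    for isl in islands:
        if isl.name not in annotated:
            rows.append(
                {
                    "island": isl.name,
                    "feature_id": "",
                    "relation": "none",
                    "distance_bp": -1,
                }
            )
    return pd.DataFrame(
        rows, columns=["island", "feature_id", "relation", "distance_bp"]
    )
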