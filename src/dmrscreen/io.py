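"""File I/O: FASTA, FASTQ, GFF3, Bismark-style coverage, BED, bedGraph.

Readers convert every external coordinate convention to the internal
0-based half-open one; writers convert back.  FASTA/FASTQ parsing is
delegated to Biopython, GFF3 parsing to gffutils; the simple tabular
writers emit the dialects directly.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    CpGSiteMethylation,
    DmrScreenError,
    GeneFeature,
    GenomeSequence,
    GenomicInterval,
)


class FastaError(DmrScreenError):
    pass


class GffError(DmrScreenError):
    pass


class CoverageDialectError(DmrScreenError):
    pass


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a multi-record FASTA into GenomeSequence objects, in file order.

    Sequences are uppercased; duplicate contig ids, empty files and
    non-IUPAC characters are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaError(f"no FASTA records in {path}")
    seen: set[str] = set()
    out: list[GenomeSequence] = []
    for rec in records:
        if rec.id in seen:
            raise FastaError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            out.append(GenomeSequence(rec.id, str(rec.seq)))
        except ValueError as exc:
            raise FastaError(str(exc)) from exc
    return out


def write_fasta(path: str | Path, genomes: Iterable[GenomeSequence]) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.contig_id, description="")
        for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read single-end FASTQ as (read_id, sequence) pairs; qualities dropped."""
    return [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]]) -> None:
    """Write (read_id, sequence) pairs as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff(
    path: str | Path,
    feature_types: Sequence[str] = ("gene",),
    id_attribute: str = "ID",
) -> list[GeneFeature]:
    """Read GFF3 features of the given types, converting to 0-based half-open.

    GFF3 is 1-based inclusive: file (start, end) becomes [start-1, end).
    Records with end < start are rejected.  The feature id is taken from
    *id_attribute* (default ``ID``), falling back to a positional name.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises various parse errors
        raise GffError(f"failed to parse GFF3 {path}: {exc}") from exc

    wanted = set(feature_types)
    out: list[GeneFeature] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in wanted:
            continue
        if feat.end < feat.start:
            raise GffError(
                f"feature with end < start at {feat.seqid}:{feat.start}-{feat.end}"
            )
        ids = feat.attributes.get(id_attribute, [])
        fid = ids[0] if ids else f"{feat.featuretype}:{feat.seqid}:{feat.start}"
        strand = feat.strand if feat.strand in ("+", "-") else "."
        out.append(
            GeneFeature(
                feature_id=fid,
                interval=GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand),
                feature_type=feat.featuretype,
                attributes={k: list(v) for k, v in feat.attributes.items()},
            )
        )
    return out


def write_gff(path: str | Path, features: Iterable[GeneFeature]) -> None:
    """Write features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            iv = f.interval
            fh.write(
                "\t".join(
                    [
                        iv.contig_id,
                        "dmrscreen",
                        f.feature_type,
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand if iv.strand != "." else ".",
                        ".",
                        f"ID={f.feature_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Methylation coverage (Bismark coverage dialect and bedGraph+counts variant)

_COVERAGE_COLS = ["contig", "start", "end", "percent", "count_meth", "count_unmeth"]


def read_coverage(
    path: str | Path, dialect: str = "bismark"
) -> list[CpGSiteMethylation]:
    """Read per-CpG methylation counts from a coverage TSV.

    ``bismark`` dialect: 6 columns (contig, start, end, percent, count_meth,
    count_unmeth) with 1-based positions.  ``bedgraph`` dialect: same six
    columns but 0-based half-open start/end.  The percent column is ignored
    and recomputed from the counts; a disagreement beyond 0.5 points draws
    a warning and the counts win.  Rows with zero total reads are dropped.
    """
    if dialect not in ("bismark", "bedgraph"):
        raise ValueError(f"unknown coverage dialect {dialect!r}")
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            dtype={0: str},
        )
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 6:
        raise CoverageDialectError(
            f"{path}: expected 6 tab-separated columns, found {df.shape[1]}"
        )
    df.columns = _COVERAGE_COLS
    if (df["count_meth"] < 0).any() or (df["count_unmeth"] < 0).any():
        bad = df.index[(df["count_meth"] < 0) | (df["count_unmeth"] < 0)][0]
        raise CoverageDialectError(f"{path}: negative read count on line {bad + 1}")

    cov = df["count_meth"] + df["count_unmeth"]
    covered = df[cov > 0].copy()
    total = covered["count_meth"] + covered["count_unmeth"]
    recomputed = 100.0 * covered["count_meth"] / total
    drift = (covered["percent"] - recomputed).abs()
    if (drift > 0.5).any():
        n_bad = int((drift > 0.5).sum())
        warnings.warn(
            f"{path}: percent column disagrees with counts by >0.5 on "
            f"{n_bad} line(s); counts take precedence",
            stacklevel=2,
        )
    offset = 1 if dialect == "bismark" else 0
    return [
        CpGSiteMethylation(
            contig_id=str(row.contig),
            pos=int(row.start) - offset,
            count_meth=int(row.count_meth),
            count_unmeth=int(row.count_unmeth),
        )
        for row in covered.itertuples()
    ]


def write_coverage(
    path: str | Path,
    sites: Iterable[CpGSiteMethylation],
    dialect: str = "bismark",
) -> None:
    """Write sites in the Bismark coverage dialect (or 0-based bedgraph)."""
    if dialect not in ("bismark", "bedgraph"):
        raise ValueError(f"unknown coverage dialect {dialect!r}")
    offset = 1 if dialect == "bismark" else 0
    with open(path, "w") as fh:
        for s in sites:
            if s.coverage == 0:
                continue
            start = s.pos + offset
            end = s.pos + 1
            fh.write(
                f"{s.contig_id}\t{start}\t{end}\t{s.percent:.6g}\t"
                f"{s.count_meth}\t{s.count_unmeth}\n"
            )


# ---------------------------------------------------------------------------
# Amplicon definitions (JSON)


def write_amplicon_json(path: str | Path, amplicon, snp=None) -> None:
    """Write an amplicon definition (and optionally its SNP) as JSON."""
    import json

    payload = {
        "name": amplicon.name,
        "reference": amplicon.reference,
        "contig_id": amplicon.contig_id,
        "start": amplicon.start,
        "cpg_offsets": list(amplicon.cpg_offsets),
        "snp_offset": amplicon.snp_offset,
    }
    if snp is not None:
        payload["snp"] = {
            "pos": snp.pos,
            "maternal_allele": snp.maternal_allele,
            "paternal_allele": snp.paternal_allele,
            "informative": snp.informative,
        }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_amplicon_json(path: str | Path):
    """Read an amplicon definition; returns (BisulfiteAmplicon, SnpSpec|None)."""
    import json

    from .phasing import BisulfiteAmplicon, SnpSpec

    payload = json.loads(Path(path).read_text())
    snp_payload = payload.pop("snp", None)
    amplicon = BisulfiteAmplicon(
        name=payload["name"],
        reference=payload["reference"],
        contig_id=payload["contig_id"],
        start=payload["start"],
        cpg_offsets=tuple(payload["cpg_offsets"]),
        snp_offset=payload["snp_offset"],
    )
    snp = None
    if snp_payload is not None:
        snp = SnpSpec(
            contig_id=amplicon.contig_id,
            pos=snp_payload["pos"],
            maternal_allele=snp_payload["maternal_allele"],
            paternal_allele=snp_payload["paternal_allele"],
            informative=snp_payload.get("informative", True),
        )
    return amplicon, snp


# ---------------------------------------------------------------------------
# BED / bedGraph


def write_bed(path: str | Path, islands) -> None:
    """Write CpG islands as BED: contig, start, end, name, n_cpg, density."""
    with open(path, "w") as fh:
        for i, isl in enumerate(islands, start=1):
            iv = isl.interval
            fh.write(
                f"{iv.contig_id}\t{iv.start}\t{iv.end}\tCGI_{i}\t"
                f"{isl.n_cpg}\t{isl.density_pct:.4f}\n"
            )


def write_bedgraph(path: str | Path, tracks) -> None:
    """Write density tracks as bedGraph (percent per window)."""
    with open(path, "w") as fh:
        for track in np.atleast_1d(tracks):
            w = track.window_bp
            for i, v in enumerate(track.values):
                start = i * w
                end = min(start + w, track.contig_length)
                fh.write(f"{track.contig_id}\t{start}\t{end}\t{v:.4f}\n")
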