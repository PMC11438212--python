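"""Shared domain types and coordinate conventions.

All coordinates inside the package are 0-based half-open on the forward
strand.  File dialects that use other conventions (GFF3: 1-based inclusive;
Bismark coverage: 1-based) are converted at the I/O boundary and nowhere
else.

A CpG dinucleotide is identified by the position of its C on the forward
strand; the reverse-strand CpG at the same locus is the same biological
site and is never counted twice.  ``N`` and IUPAC ambiguity codes never
participate in a CpG (conservative density estimation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")

STRANDS = ("+", "-", ".")


class DmrScreenError(Exception):
    """Base class for errors raised by this package."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a contig, 0-based."""

    contig_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig_id}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence; uppercased and alphabet-checked on construction."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) == 0:
            raise ValueError(f"contig {self.contig_id!r} has empty sequence")
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"contig {self.contig_id!r} contains non-IUPAC characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def cpg_positions(sequence: str) -> np.ndarray:
    """Positions ``i`` with ``sequence[i] == 'C'`` and ``sequence[i+1] == 'G'``.

    Returns the forward-strand C position of every CpG dinucleotide as an
    int64 array.  Ambiguity codes and N break CpGs by construction since
    only literal C followed by literal G matches.
    """
    if len(sequence) < 2:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    mask = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    return np.flatnonzero(mask).astype(np.int64)


def count_cpgs(sequence: str) -> int:
    """Number of CpG dinucleotides in *sequence*."""
    return int(cpg_positions(sequence).size)


@dataclass(frozen=True)
class CpGSiteMethylation:
    """Read counts at one CpG site (keyed by the forward-strand C)."""

    contig_id: str
    pos: int
    count_meth: int
    count_unmeth: int

    def __post_init__(self) -> None:
        if self.count_meth < 0 or self.count_unmeth < 0:
            raise ValueError(
                f"negative read count at {self.contig_id}:{self.pos}"
            )

    @property
    def coverage(self) -> int:
        return self.count_meth + self.count_unmeth

    @property
    def percent(self) -> float:
        cov = self.coverage
        if cov == 0:
            raise ValueError(f"uncovered site {self.contig_id}:{self.pos}")
        return 100.0 * self.count_meth / cov


@dataclass(frozen=True)
class GeneFeature:
    """An annotated feature (by default a gene) with a genomic interval."""

    feature_id: str
    interval: GenomicInterval
    feature_type: str = "gene"
    attributes: dict = field(default_factory=dict, compare=False)
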