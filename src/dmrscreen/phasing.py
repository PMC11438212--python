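"""Parent-of-origin analysis: SNP inference, read splitting, CpG calling.

Workflow mirrored here: genotype a mother/offspring pair at a SNP inside
the assayed amplicon; when the mother is homozygous and the offspring
heterozygous the offspring's two alleles can be assigned to parents.
Bisulfite amplicon reads (or Sanger clone sequences) are then partitioned
by the base observed at the SNP, CpG methylation is called per read in
QUMA style (C = methylated, T = unmethylated at each assayed CpG), and
per-parent methylation is tallied.  A parallel path counts allele-specific
expression from unconverted cDNA amplicon reads.

Bisulfite chemistry constrains which SNPs are usable: on forward-strand
converted reads every unmethylated C reads as T, so a C allele at a
non-CpG SNP is *expected* to read as T.  Read matching therefore compares
against the bisulfite-expected base of each allele, and a SNP whose two
alleles share an expected base (C/T on forward-strand reads, G/A on
reverse) is rejected outright rather than silently misassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import DmrScreenError

MATERNAL = "maternal"
PATERNAL = "paternal"
UNASSIGNED = "unassigned"

DNA = frozenset("ACGT")


class ConfoundedSnpError(DmrScreenError):
    """SNP alleles indistinguishable on bisulfite-converted reads."""


class GenotypeInconsistencyError(DmrScreenError):
    """Offspring genotype impossible given the maternal genotype."""


class AlignmentError(DmrScreenError):
    """Sequence cannot be anchored to the amplicon reference."""


@dataclass(frozen=True)
class SnpSpec:
    contig_id: str
    pos: int  # 0-based genomic position
    maternal_allele: str
    paternal_allele: str
    informative: bool = True
    reason: str = ""  # why uninformative, when informative is False

    def __post_init__(self) -> None:
        for a in (self.maternal_allele, self.paternal_allele):
            if a not in DNA:
                raise ValueError(f"invalid allele {a!r}")
        if self.informative and self.maternal_allele == self.paternal_allele:
            raise ValueError("informative SNP requires distinct alleles")


@dataclass(frozen=True)
class BisulfiteAmplicon:
    """An amplicon anchored on the genome, with its assayed CpGs and SNP.

    ``reference`` is the unconverted forward-strand sequence; offsets are
    0-based within the amplicon.  The SNP must not sit on or adjacent to an
    assayed CpG C (it would create or destroy the dinucleotide).
    """

    name: str
    reference: str
    contig_id: str
    start: int  # genomic start of the amplicon
    cpg_offsets: tuple[int, ...]
    snp_offset: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference", self.reference.upper())
        n = len(self.reference)
        for off in self.cpg_offsets:
            if not 0 <= off < n - 1:
                raise ValueError(f"CpG offset {off} out of amplicon range")
            if abs(off - self.snp_offset) <= 1:
                raise ValueError(
                    f"SNP offset {self.snp_offset} within 1 bp of CpG offset {off}"
                )
        if not 0 <= self.snp_offset < n:
            raise ValueError("SNP offset out of amplicon range")

    @property
    def non_cpg_c_offsets(self) -> tuple[int, ...]:
        """Reference C positions outside assayed CpGs and the SNP: the
        conversion-QC positions (all should read T after full conversion)."""
        cpg = set(self.cpg_offsets)
        return tuple(
            i
            for i, b in enumerate(self.reference)
            if b == "C" and i not in cpg and i != self.snp_offset
        )


@dataclass
class ReadCalls:
    """QUMA-style per-read (or per-clone) CpG calls with conversion QC."""

    read_id: str
    calls: dict[int, int | None]  # cpg_offset -> 1 meth / 0 unmeth / None no-call
    n_meth: int
    n_unmeth: int
    n_nocall: int
    conversion_failure_est: float | None  # None when no QC position covered
    mismatch_frac: float
    qc_pass: bool
    qc_c: int = 0  # unconverted C count at QC positions
    qc_total: int = 0  # QC positions covered and read as C or T

    @property
    def percent_meth(self) -> float:
        called = self.n_meth + self.n_unmeth
        if called == 0:
            raise ValueError(f"read {self.read_id} has no called CpG sites")
        return 100.0 * self.n_meth / called


@dataclass
class AllelicMethylationResult:
    n_maternal: int
    n_paternal: int
    n_unassigned: int
    maternal_site_counts: dict[int, tuple[int, int]]  # offset -> (meth, unmeth)
    paternal_site_counts: dict[int, tuple[int, int]]
    maternal_pct: float | None  # read-weighted across sites; None if no reads
    paternal_pct: float | None


@dataclass
class AllelicExpressionResult:
    count_maternal: int
    count_paternal: int
    count_other: int  # error mass: reads with neither allele at the SNP
    maternal_fraction: float | None  # over the two alleles
    paternal_fraction: float | None
    call: str  # monoallelic_maternal / monoallelic_paternal /
    #            monoallelic_unknown_parent / biallelic / ambiguous /
    #            insufficient_coverage


# ---------------------------------------------------------------------------
# Trio genotyping


def infer_parental_alleles(
    maternal_genotype: tuple[str, str],
    offspring_genotype: tuple[str, str],
    contig_id: str = "",
    pos: int = 0,
) -> SnpSpec:
    """Assign the offspring's alleles to parents from unordered genotypes.

    Informative iff the mother is homozygous X/X and the offspring
    heterozygous X/Y: then maternal=X and paternal=Y.  A heterozygous
    mother or homozygous offspring is uninformative (with a reason code);
    an offspring sharing no allele with a homozygous mother is a genotyping
    inconsistency and raises.
    """
    mg = tuple(sorted(b.upper() for b in maternal_genotype))
    og = tuple(sorted(b.upper() for b in offspring_genotype))
    for b in mg + og:
        if b not in DNA:
            raise ValueError(f"invalid genotype base {b!r}")
    if mg[0] != mg[1]:
        # the offspring's alleles are still known (parent assignment is not);
        # keep them so expression phasing can run in unknown-parent mode
        return SnpSpec(contig_id, pos, og[0], og[1], informative=False,
                       reason="mother_heterozygous")
    x = mg[0]
    if x not in og:
        raise GenotypeInconsistencyError(
            f"offspring {og} shares no allele with homozygous mother {x}/{x}"
        )
    if og[0] == og[1]:
        return SnpSpec(contig_id, pos, x, x, informative=False, reason="no_snp")
    y = og[1] if og[0] == x else og[0]
    return SnpSpec(contig_id, pos, x, y, informative=True)


# ---------------------------------------------------------------------------
# Bisulfite read splitting


def bisulfite_expected_base(allele: str, strand: str = "+") -> str:
    """The base an allele is expected to show on converted reads.

    A non-CpG C is unmethylated and converts, so it reads T on the forward
    strand; on reverse-strand reads the complementary logic turns G into A.
    """
    if strand == "+":
        return "T" if allele == "C" else allele
    if strand == "-":
        return "A" if allele == "G" else allele
    raise ValueError(f"invalid strand {strand!r}")


def split_reads_by_allele(
    reads: list[tuple[str, str]],
    amplicon: BisulfiteAmplicon,
    snp: SnpSpec,
    strand: str = "+",
) -> dict[str, list[tuple[str, str]]]:
    """Partition bisulfite reads by the base at the amplicon SNP.

    Returns a dict with keys ``maternal``, ``paternal``, ``unassigned``;
    every input read lands in exactly one bin.  Reads too short to cover
    the SNP, or showing neither allele's expected base, are unassigned.
    Raises ConfoundedSnpError when the two alleles are indistinguishable
    after conversion.
    """
    exp_mat = bisulfite_expected_base(snp.maternal_allele, strand)
    exp_pat = bisulfite_expected_base(snp.paternal_allele, strand)
    if exp_mat == exp_pat:
        raise ConfoundedSnpError(
            f"SNP {snp.maternal_allele}/{snp.paternal_allele} is unresolvable "
            f"on {strand}-strand bisulfite reads (both read as {exp_mat})"
        )
    off = amplicon.snp_offset
    out: dict[str, list[tuple[str, str]]] = {
        MATERNAL: [], PATERNAL: [], UNASSIGNED: []
    }
    for rid, seq in reads:
        seq = seq.upper()
        if len(seq) <= off:
            out[UNASSIGNED].append((rid, seq))
            continue
        base = seq[off]
        if base == exp_mat:
            out[MATERNAL].append((rid, seq))
        elif base == exp_pat:
            out[PATERNAL].append((rid, seq))
        else:
            out[UNASSIGNED].append((rid, seq))
    return out


# ---------------------------------------------------------------------------
# QUMA-style CpG calling


def call_cpg_methylation(
    read_id: str,
    sequence: str,
    amplicon: BisulfiteAmplicon,
    conversion_failure_threshold: float = 0.05,
    nocall_threshold: float = 0.20,
    mismatch_tolerance: float = 0.10,
) -> ReadCalls:
    """Call methylation at each assayed CpG of one anchored sequence.

    The sequence must be anchored at amplicon offset 0 (clones pre-trimmed
    of vector); it may be shorter than the reference, in which case sites
    beyond its end are no-calls, but may not be longer.  At each CpG
    offset: C = methylated, T = unmethylated, anything else = no-call.
    Reference Cs outside CpGs and the SNP estimate conversion failure
    (fraction still read as C); the read fails QC when that estimate
    exceeds *conversion_failure_threshold*, the no-call fraction exceeds
    *nocall_threshold*, or the non-C mismatch fraction exceeds
    *mismatch_tolerance*.
    """
    seq = sequence.upper()
    ref = amplicon.reference
    if len(seq) > len(ref):
        raise AlignmentError(
            f"read {read_id} ({len(seq)} bp) longer than amplicon "
            f"reference ({len(ref)} bp); exact-offset anchoring only"
        )

    calls: dict[int, int | None] = {}
    for off in amplicon.cpg_offsets:
        if off >= len(seq):
            calls[off] = None
        elif seq[off] == "C":
            calls[off] = 1
        elif seq[off] == "T":
            calls[off] = 0
        else:
            calls[off] = None
    n_meth = sum(1 for v in calls.values() if v == 1)
    n_unmeth = sum(1 for v in calls.values() if v == 0)
    n_nocall = sum(1 for v in calls.values() if v is None)

    n_c = n_t = 0
    for off in amplicon.non_cpg_c_offsets:
        if off >= len(seq):
            continue
        if seq[off] == "C":
            n_c += 1
        elif seq[off] == "T":
            n_t += 1
    conv_fail = n_c / (n_c + n_t) if (n_c + n_t) else None

    # mismatches outside CpG, SNP and convertible-C positions
    special = set(amplicon.cpg_offsets) | set(amplicon.non_cpg_c_offsets)
    special.add(amplicon.snp_offset)
    n_cmp = n_mm = 0
    for i in range(len(seq)):
        if i in special:
            continue
        n_cmp += 1
        if seq[i] != ref[i]:
            n_mm += 1
    mismatch_frac = n_mm / n_cmp if n_cmp else 0.0

    nocall_frac = n_nocall / len(calls) if calls else 0.0
    qc_pass = (
        (conv_fail is None or conv_fail <= conversion_failure_threshold)
        and nocall_frac <= nocall_threshold
        and mismatch_frac <= mismatch_tolerance
    )
    return ReadCalls(
        read_id=read_id,
        calls=calls,
        n_meth=n_meth,
        n_unmeth=n_unmeth,
        n_nocall=n_nocall,
        conversion_failure_est=conv_fail,
        mismatch_frac=mismatch_frac,
        qc_pass=qc_pass,
        qc_c=n_c,
        qc_total=n_c + n_t,
    )


def estimate_conversion_failure(calls: list[ReadCalls]) -> float | None:
    """Pooled conversion-failure rate across reads (QC positions only)."""
    num = den = 0
    for rc in calls:
        num += rc.qc_c
        den += rc.qc_total
    return num / den if den else None


def per_allele_methylation(
    partition: dict[str, list[tuple[str, str]]],
    amplicon: BisulfiteAmplicon,
    require_qc: bool = True,
    **qc_kwargs,
) -> tuple[AllelicMethylationResult, dict[str, list[ReadCalls]]]:
    """Call CpGs on each partitioned read and tally per-parent methylation.

    Returns the tallied result plus the per-read call objects (QC failures
    included in the returned calls but excluded from tallies when
    *require_qc* is set).  Read-count conservation holds: maternal +
    paternal + unassigned equals the input total.
    """
    all_calls: dict[str, list[ReadCalls]] = {MATERNAL: [], PATERNAL: []}
    site_counts: dict[str, dict[int, list[int]]] = {MATERNAL: {}, PATERNAL: {}}
    n_used = {MATERNAL: 0, PATERNAL: 0}
    for side in (MATERNAL, PATERNAL):
        for rid, seq in partition.get(side, []):
            rc = call_cpg_methylation(rid, seq, amplicon, **qc_kwargs)
            all_calls[side].append(rc)
            if require_qc and not rc.qc_pass:
                continue
            n_used[side] += 1
            for off, v in rc.calls.items():
                if v is None:
                    continue
                cnt = site_counts[side].setdefault(off, [0, 0])
                cnt[0 if v == 1 else 1] += 1

    def overall(side: str) -> float | None:
        m = sum(c[0] for c in site_counts[side].values())
        u = sum(c[1] for c in site_counts[side].values())
        return 100.0 * m / (m + u) if (m + u) else None

    result = AllelicMethylationResult(
        n_maternal=len(partition.get(MATERNAL, [])),
        n_paternal=len(partition.get(PATERNAL, [])),
        n_unassigned=len(partition.get(UNASSIGNED, [])),
        maternal_site_counts={k: tuple(v) for k, v in site_counts[MATERNAL].items()},
        paternal_site_counts={k: tuple(v) for k, v in site_counts[PATERNAL].items()},
        maternal_pct=overall(MATERNAL),
        paternal_pct=overall(PATERNAL),
    )
    return result, all_calls


def lollipop_matrix(calls: dict[str, list[ReadCalls]], amplicon: BisulfiteAmplicon):
    """QUMA-style clone-by-site matrix: 1 methylated, 0 unmethylated, NA no-call."""
    import pandas as pd

    rows = {}
    for side in (MATERNAL, PATERNAL):
        for rc in calls.get(side, []):
            rows[f"{side}:{rc.read_id}"] = {
                off: rc.calls.get(off) for off in amplicon.cpg_offsets
            }
    return pd.DataFrame.from_dict(rows, orient="index")[list(amplicon.cpg_offsets)]


# ---------------------------------------------------------------------------
# Allele-specific expression


def count_allele_expression(
    reads: list[tuple[str, str]],
    snp_offset: int,
    snp: SnpSpec,
    major_threshold: float = 0.85,
    biallelic_range: tuple[float, float] = (0.35, 0.65),
    min_reads: int = 20,
) -> AllelicExpressionResult:
    """Tally unconverted cDNA amplicon reads per allele at the SNP.

    Fractions are over the two expected alleles; reads showing any other
    base are reported separately as error mass.  The call is monoallelic
    when the major allele's fraction reaches *major_threshold*, biallelic
    when both fractions fall inside *biallelic_range*, ambiguous otherwise;
    with an uninformative SNP (parents unknown) monoallelic calls become
    ``monoallelic_unknown_parent``.  Fewer than *min_reads* informative
    reads yields an insufficient-coverage result.
    """
    n_mat = n_pat = n_other = 0
    for _, seq in reads:
        seq = seq.upper()
        if len(seq) <= snp_offset:
            n_other += 1
            continue
        base = seq[snp_offset]
        if base == snp.maternal_allele and base == snp.paternal_allele:
            # uninformative SNP stores the same base twice; count as maternal
            # bin (labels are arbitrary for unknown parents)
            n_mat += 1
        elif base == snp.maternal_allele:
            n_mat += 1
        elif base == snp.paternal_allele:
            n_pat += 1
        else:
            n_other += 1

    total = n_mat + n_pat
    if total < min_reads:
        return AllelicExpressionResult(
            n_mat, n_pat, n_other, None, None, "insufficient_coverage"
        )
    f_mat = n_mat / total
    f_pat = n_pat / total
    lo, hi = biallelic_range
    if f_mat >= major_threshold:
        call = "monoallelic_maternal" if snp.informative else "monoallelic_unknown_parent"
    elif f_pat >= major_threshold:
        call = "monoallelic_paternal" if snp.informative else "monoallelic_unknown_parent"
    elif lo <= f_mat <= hi and lo <= f_pat <= hi:
        call = "biallelic"
    else:
        call = "ambiguous"
    return AllelicExpressionResult(n_mat, n_pat, n_other, f_mat, f_pat, call)
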