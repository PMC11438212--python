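"""Synthetic diploid methylome generator with known truth for every stage.

The generator emulates the data structure the screen assumes: a genome
with CpG-depleted background (default 1% CpG density, typical of bulk
vertebrate sequence after historical CpG decay) carrying planted CpG
islands of configurable length and density, one synthetic gene per island
with the island at the gene start; per-CpG binomial read coverage under
per-allele methylation states; and SNP-bearing bisulfite amplicon reads
drawn from two parental haplotypes.

CpG placement is deterministic given the seed: island CpGs sit on an even
lattice so the planted density is exact, which keeps the density-gate
tests sharp.  Background CpGs default to fully methylated, mirroring
vertebrate genomes where non-island CpGs are methylated.

Per-read methylation calls fold in bisulfite conversion failure and
sequencing error: a methylated C is protected (reads methylated unless a
sequencing error flips it) while an unmethylated C reads methylated when
conversion fails or an error strikes a converted T.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core import CpGSiteMethylation, DmrScreenError, GeneFeature, GenomeSequence, GenomicInterval, cpg_positions
from .phasing import BisulfiteAmplicon, SnpSpec, bisulfite_expected_base

_B = {b: np.uint8(ord(b)) for b in "ACGT"}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

STATE_METH = "methylated"
STATE_UNMETH = "unmethylated"
STATE_IMP_MAT = "imprinted_maternal_methylated"
STATE_IMP_PAT = "imprinted_paternal_methylated"
STATE_NOISY = "noisy"

STATES = (STATE_METH, STATE_UNMETH, STATE_IMP_MAT, STATE_IMP_PAT, STATE_NOISY)


class ConfigError(DmrScreenError):
    pass


def allele_meth_probs(state: str, noise_level: float = 0.5) -> tuple[float, float]:
    """(maternal, paternal) true methylation probability for a state."""
    table = {
        STATE_METH: (1.0, 1.0),
        STATE_UNMETH: (0.0, 0.0),
        STATE_IMP_MAT: (1.0, 0.0),
        STATE_IMP_PAT: (0.0, 1.0),
        STATE_NOISY: (noise_level, noise_level),
    }
    if state not in table:
        raise ConfigError(f"unknown island state {state!r}")
    return table[state]


@dataclass(frozen=True)
class SnpPlan:
    """A SNP linked to an island; offset None = auto-place mid island."""

    offset_bp: int | None = None
    maternal_allele: str = "A"
    paternal_allele: str = "G"
    informative: bool = True

    def __post_init__(self) -> None:
        exp_m = bisulfite_expected_base(self.maternal_allele)
        exp_p = bisulfite_expected_base(self.paternal_allele)
        if exp_m == exp_p:
            raise ConfigError(
                f"SNP {self.maternal_allele}/{self.paternal_allele} is "
                f"bisulfite-confounded (both read as {exp_m} after conversion)"
            )


@dataclass(frozen=True)
class IslandSpec:
    length_bp: int = 2000  # multiple of tile_bp
    density_pct: float = 4.8
    state: str = STATE_IMP_MAT
    noise_level: float = 0.5
    snp: SnpPlan | None = None


def default_islands() -> list[IslandSpec]:
    """One island of each methylation class, imprinted one SNP-linked."""
    return [
        IslandSpec(state=STATE_METH),
        IslandSpec(state=STATE_UNMETH),
        IslandSpec(state=STATE_IMP_MAT, snp=SnpPlan()),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_contigs: int = 1
    contig_length_bp: int = 60_000
    background_cpg_density_pct: float = 1.0
    islands: list[IslandSpec] = field(default_factory=default_islands)
    depth: float = 30.0  # mean reads per CpG site
    conversion_rate: float = 0.99
    seq_error_rate: float = 0.001
    tile_bp: int = 1000
    density_multiplier: int = 1
    gene_length_bp: int = 8000
    gene_geometry: str = "within"  # island at gene start; or "near_start"
    first_island_offset_bp: int = 5000
    island_spacing_bp: int = 6000  # background between islands (>= 2 kb)
    background_state: str = STATE_METH

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if not 0 < self.conversion_rate <= 1:
            raise ConfigError("conversion_rate must be in (0, 1]")
        if not 0 <= self.seq_error_rate < 1:
            raise ConfigError("seq_error_rate must be in [0, 1)")
        if self.island_spacing_bp < 2000:
            raise ConfigError("islands must be separated by >= 2 kb")
        if not 0 <= self.background_cpg_density_pct <= 100:
            raise ConfigError("background density must be a percent")
        for isl in self.islands:
            if isl.length_bp % self.tile_bp != 0 or isl.length_bp < 2 * self.tile_bp:
                raise ConfigError(
                    "island length must be a multiple of tile_bp and span >= 2 tiles"
                )
            if not 0 <= isl.density_pct <= 100:
                raise ConfigError("island density must be a percent")
            allele_meth_probs(isl.state, isl.noise_level)
        if self.gene_geometry not in ("within", "near_start"):
            raise ConfigError(f"unknown gene_geometry {self.gene_geometry!r}")


@dataclass
class PlantedIsland:
    island_id: str
    contig_id: str
    start: int
    end: int
    state: str
    n_cpg: int
    density_pct: float
    maternal_p: float
    paternal_p: float
    cpg_positions: list[int]
    snp: dict | None = None  # pos, maternal_allele, paternal_allele, informative

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.contig_id, self.start, self.end)


@dataclass
class TruthTable:
    """Everything needed to score recovery without re-reading the config."""

    contigs: dict[str, int]
    islands: list[PlantedIsland]
    genes: list[dict]
    background_state: str
    conversion_rate: float
    seq_error_rate: float
    depth: float

    def island_by_id(self, island_id: str) -> PlantedIsland:
        for isl in self.islands:
            if isl.island_id == island_id:
                return isl
        raise KeyError(island_id)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        payload["islands"] = [PlantedIsland(**d) for d in payload["islands"]]
        return cls(**payload)


# ---------------------------------------------------------------------------
# Genome generation


def _island_layout(config: SimulationConfig) -> list[tuple[int, int]]:
    """(start, end) for each island on contig 0, tile-aligned."""
    t = config.tile_bp
    start = (config.first_island_offset_bp // t) * t
    layout = []
    for isl in config.islands:
        end = start + isl.length_bp
        layout.append((start, end))
        start = -(-(end + config.island_spacing_bp) // t) * t
    if layout and layout[-1][1] + 2000 > config.contig_length_bp:
        raise ConfigError(
            f"islands do not fit: need {layout[-1][1] + 2000} bp, "
            f"contig is {config.contig_length_bp} bp"
        )
    return layout


def _plant_island(
    arr: np.ndarray, start: int, length: int, density_pct: float, k: int
) -> np.ndarray:
    """Plant CpGs on an even lattice; returns planted C positions."""
    n = int(round(density_pct / 100.0 * length / k))
    if n == 0:
        return np.empty(0, dtype=np.int64)
    step = length / n
    if step < 2:
        raise ConfigError(f"island density {density_pct}% too high to place CpGs")
    pos = start + np.floor(np.arange(n) * step).astype(np.int64)
    arr[pos] = _B["C"]
    arr[pos + 1] = _B["G"]
    return pos


def _destroy_cpgs(arr: np.ndarray) -> None:
    mask = (arr[:-1] == _B["C"]) & (arr[1:] == _B["G"])
    arr[1:][mask] = _B["A"]


def _place_snp(
    arr: np.ndarray,
    island_start: int,
    island_end: int,
    planted: np.ndarray,
    plan: SnpPlan,
) -> int:
    """Write the maternal allele into the reference; return the SNP position.

    The SNP must sit at least 2 bp from any planted CpG C so neither allele
    can create or destroy an assayed dinucleotide; neighbouring bases are
    adjusted when an allele could otherwise form a CpG on one haplotype.
    """
    if plan.offset_bp is None:
        # auto-place mid island, centred in the widest local lattice gap
        mid = (island_start + island_end) // 2
        gaps = np.searchsorted(planted, mid)
        left = planted[gaps - 1] if gaps > 0 else island_start
        right = planted[gaps] if gaps < planted.size else island_end
        pos = int((left + right) // 2)
    else:
        pos = island_start + plan.offset_bp
    if not island_start <= pos < island_end:
        raise ConfigError("SNP offset falls outside the island")
    if planted.size and np.min(np.abs(planted - pos)) <= 1:
        raise ConfigError(
            "SNP offset collides with an assayed CpG; pick a position >=2 bp away"
        )
    arr[pos] = _B[plan.maternal_allele]
    # neither haplotype may gain a CpG at the SNP
    for allele in (plan.maternal_allele, plan.paternal_allele):
        if allele == "G" and arr[pos - 1] == _B["C"]:
            arr[pos - 1] = _B["A"]
        if allele == "C" and arr[pos + 1] == _B["G"]:
            arr[pos + 1] = _B["T"]
    return pos


def generate_genome(
    config: SimulationConfig,
) -> tuple[list[GenomeSequence], list[GeneFeature], TruthTable]:
    """Generate the synthetic genome, gene annotation and truth table.

    Deterministic for a given config+seed (byte-identical sequences).
    Islands are planted on the first contig; further contigs are pure
    background.  If random background CpGs happen to produce two adjacent
    qualifying background tiles the contig is resampled (bounded retries),
    so a zero-island contig contains no detectable island.
    """
    k = config.density_multiplier
    t = config.tile_bp
    layout = _island_layout(config)

    genomes: list[GenomeSequence] = []
    genes: list[GeneFeature] = []
    planted_islands: list[PlantedIsland] = []
    contigs: dict[str, int] = {}

    for ci in range(config.n_contigs):
        contig_id = f"contig_{ci}"
        n = config.contig_length_bp
        contigs[contig_id] = n
        contig_layout = layout if ci == 0 else []
        for attempt in range(20):
            rng = np.random.default_rng((config.seed, 101, ci, attempt))
            arr = _BASES[rng.integers(0, 4, n)]
            _destroy_cpgs(arr)

            planted_per_island: list[np.ndarray] = []
            snp_positions: list[int | None] = []
            for (start, end), spec in zip(contig_layout, config.islands):
                pos = _plant_island(arr, start, end - start, spec.density_pct, k)
                planted_per_island.append(pos)
                if spec.snp is not None:
                    snp_positions.append(
                        _place_snp(arr, start, end, pos, spec.snp)
                    )
                else:
                    snp_positions.append(None)

            # background CpGs on an even lattice outside islands/SNPs
            excluded = np.zeros(n, dtype=bool)
            for (start, end), snp_pos in zip(contig_layout, snp_positions):
                excluded[max(0, start - 1) : end] = True
                if snp_pos is not None:
                    excluded[max(0, snp_pos - 1) : snp_pos + 2] = True
            candidates = np.arange(0, n - 2, 2)
            candidates = candidates[~excluded[candidates]]
            bg_len = n - sum(e - s for s, e in contig_layout)
            n_bg = int(round(config.background_cpg_density_pct / 100.0 * bg_len / k))
            if n_bg > candidates.size:
                raise ConfigError("background density too high for lattice placement")
            chosen = np.sort(rng.choice(candidates, size=n_bg, replace=False))
            arr[chosen] = _B["C"]
            arr[chosen + 1] = _B["G"]

            # reject contigs where background alone forms a detectable island
            all_pos = np.flatnonzero(
                (arr[:-1] == _B["C"]) & (arr[1:] == _B["G"])
            )
            n_full = n // t
            counts = np.bincount(
                all_pos[all_pos < n_full * t] // t, minlength=n_full
            )
            qualify = 100.0 * k * counts / t > 3.0
            island_tiles = np.zeros(n_full, dtype=bool)
            for start, end in contig_layout:
                island_tiles[start // t : end // t] = True
            bg_qualify = qualify & ~island_tiles
            if not np.any(bg_qualify[:-1] & bg_qualify[1:]):
                break
        else:
            raise ConfigError(
                "could not generate background free of spurious islands"
            )

        genomes.append(GenomeSequence(contig_id, arr.tobytes().decode("ascii")))

        for idx, ((start, end), spec, pos, snp_pos) in enumerate(
            zip(contig_layout, config.islands, planted_per_island, snp_positions)
        ):
            mat_p, pat_p = allele_meth_probs(spec.state, spec.noise_level)
            island_id = f"island_{idx}"
            snp_dict = None
            if snp_pos is not None:
                snp_dict = {
                    "pos": int(snp_pos),
                    "maternal_allele": spec.snp.maternal_allele,
                    "paternal_allele": spec.snp.paternal_allele,
                    "informative": spec.snp.informative,
                }
            planted_islands.append(
                PlantedIsland(
                    island_id=island_id,
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    state=spec.state,
                    n_cpg=int(pos.size),
                    density_pct=100.0 * k * pos.size / (end - start),
                    maternal_p=mat_p,
                    paternal_p=pat_p,
                    cpg_positions=[int(p) for p in pos],
                    snp=snp_dict,
                )
            )
            # one synthetic gene per island, island at the gene start
            if config.gene_geometry == "within":
                g_start = start
            else:  # near_start: gene begins 1 kb downstream of the island
                g_start = end + 1000
            g_end = min(g_start + config.gene_length_bp, n)
            genes.append(
                GeneFeature(
                    feature_id=f"gene_{idx}",
                    interval=GenomicInterval(contig_id, g_start, g_end, "+"),
                )
            )

    truth = TruthTable(
        contigs=contigs,
        islands=planted_islands,
        genes=[
            {
                "feature_id": g.feature_id,
                "contig_id": g.interval.contig_id,
                "start": g.interval.start,
                "end": g.interval.end,
                "strand": g.interval.strand,
            }
            for g in genes
        ],
        background_state=config.background_state,
        conversion_rate=config.conversion_rate,
        seq_error_rate=config.seq_error_rate,
        depth=config.depth,
    )
    return genomes, genes, truth


# ---------------------------------------------------------------------------
# Coverage simulation


def methylated_call_prob(
    p_true: float, conversion_rate: float, seq_error_rate: float
) -> float:
    """Probability one read reports 'methylated' at a site.

    A truly methylated C is protected from conversion and reads C unless a
    sequencing error strikes; a truly unmethylated C reads C when
    conversion fails (no error) or converts but an error restores a C-like
    call.
    """
    e = seq_error_rate
    conv = conversion_rate
    return p_true * (1 - e) + (1 - p_true) * ((1 - conv) * (1 - e) + conv * e)


def simulate_coverage(
    genomes: list[GenomeSequence],
    truth: TruthTable,
    config: SimulationConfig,
) -> list[CpGSiteMethylation]:
    """Per-CpG read counts across the whole genome.

    Total coverage per site is Poisson(depth), split Binomial(., 1/2)
    between the two alleles; each read's call is Bernoulli with the
    state-, conversion- and error-dependent probability.  Sites drawing
    zero reads are uncovered and omitted.
    """
    rng = np.random.default_rng((config.seed, 202))
    bg_mat, bg_pat = allele_meth_probs(config.background_state)
    sites: list[CpGSiteMethylation] = []
    for g in genomes:
        pos = cpg_positions(g.sequence)
        if pos.size == 0:
            continue
        mat_p = np.full(pos.size, bg_mat)
        pat_p = np.full(pos.size, bg_pat)
        for isl in truth.islands:
            if isl.contig_id != g.contig_id:
                continue
            in_isl = (pos >= isl.start) & (pos < isl.end)
            mat_p[in_isl] = isl.maternal_p
            pat_p[in_isl] = isl.paternal_p
        cov = rng.poisson(config.depth, pos.size)
        n_mat = rng.binomial(cov, 0.5)
        pm_mat = methylated_call_prob(mat_p, config.conversion_rate, config.seq_error_rate)
        pm_pat = methylated_call_prob(pat_p, config.conversion_rate, config.seq_error_rate)
        meth = rng.binomial(n_mat, pm_mat) + rng.binomial(cov - n_mat, pm_pat)
        covered = cov > 0
        for p, c, m in zip(pos[covered], cov[covered], meth[covered]):
            sites.append(
                CpGSiteMethylation(g.contig_id, int(p), int(m), int(c - m))
            )
    return sites


# ---------------------------------------------------------------------------
# Amplicon read simulation


def build_amplicon(
    genomes: list[GenomeSequence],
    truth: TruthTable,
    island_id: str,
    halfwidth_bp: int = 150,
) -> tuple[BisulfiteAmplicon, SnpSpec]:
    """Define the bisulfite amplicon around an island's SNP.

    The amplicon covers the assayed CpGs within *halfwidth_bp* of the SNP
    plus 10 bp margins; its reference carries the maternal allele (the
    reference haplotype of the synthetic genome).
    """
    isl = truth.island_by_id(island_id)
    if isl.snp is None:
        raise ConfigError(f"island {island_id} has no SNP in its plan")
    snp_pos = isl.snp["pos"]
    seq = next(g.sequence for g in genomes if g.contig_id == isl.contig_id)
    cpgs = [c for c in isl.cpg_positions if abs(c - snp_pos) <= halfwidth_bp]
    if not cpgs:
        raise ConfigError(f"no CpGs within {halfwidth_bp} bp of the SNP")
    start = max(isl.start, min(min(cpgs), snp_pos) - 10)
    end = min(isl.end, max(max(cpgs) + 2, snp_pos + 1) + 10)
    amplicon = BisulfiteAmplicon(
        name=f"{island_id}_amplicon",
        reference=seq[start:end],
        contig_id=isl.contig_id,
        start=start,
        cpg_offsets=tuple(c - start for c in cpgs),
        snp_offset=snp_pos - start,
    )
    snp = SnpSpec(
        contig_id=isl.contig_id,
        pos=snp_pos,
        maternal_allele=isl.snp["maternal_allele"],
        paternal_allele=isl.snp["paternal_allele"],
        informative=isl.snp["informative"],
    )
    return amplicon, snp


def simulate_amplicon_reads(
    genomes: list[GenomeSequence],
    truth: TruthTable,
    config: SimulationConfig,
    island_id: str,
    n_reads: int = 200,
    read_length: int | None = None,
    maternal_fraction: float = 0.5,
) -> tuple[list[tuple[str, str]], BisulfiteAmplicon, SnpSpec, dict[str, str]]:
    """Bisulfite amplicon reads from the two parental haplotypes.

    Each read picks a haplotype (maternal with probability
    *maternal_fraction*), receives that haplotype's SNP allele, is
    bisulfite-converted in silico (methylated CpG Cs protected per the
    island state; every other C converts with ``conversion_rate``), and
    finally picks up uniform sequencing errors.  Returns the reads, the
    amplicon definition, the SNP spec and the per-read haplotype truth.
    """
    rng = np.random.default_rng((config.seed, 303))
    amplicon, snp = build_amplicon(genomes, truth, island_id)
    isl = truth.island_by_id(island_id)
    ref_arr = np.frombuffer(amplicon.reference.encode("ascii"), dtype=np.uint8).copy()
    n = ref_arr.size
    cpg_mask = np.zeros(n, dtype=bool)
    cpg_mask[list(amplicon.cpg_offsets)] = True
    p_by_hap = {"maternal": isl.maternal_p, "paternal": isl.paternal_p}
    allele_by_hap = {
        "maternal": _B[snp.maternal_allele],
        "paternal": _B[snp.paternal_allele],
    }

    reads: list[tuple[str, str]] = []
    read_truth: dict[str, str] = {}
    for i in range(n_reads):
        hap = "maternal" if rng.random() < maternal_fraction else "paternal"
        arr = ref_arr.copy()
        arr[amplicon.snp_offset] = allele_by_hap[hap]
        is_c = arr == _B["C"]
        meth = cpg_mask & (rng.random(n) < p_by_hap[hap])
        convert = is_c & ~meth & (rng.random(n) < config.conversion_rate)
        arr[convert] = _B["T"]
        if config.seq_error_rate > 0:
            err = rng.random(n) < config.seq_error_rate
            if err.any():
                idx = _CODE[arr[err]]
                shift = rng.integers(1, 4, err.sum())
                arr[err] = _BASES[(idx + shift) % 4]
        if read_length is not None:
            arr = arr[:read_length]
        rid = f"{island_id}_read_{i}"
        reads.append((rid, arr.tobytes().decode("ascii")))
        read_truth[rid] = hap
    return reads, amplicon, snp, read_truth


def simulate_expression_reads(
    amplicon: BisulfiteAmplicon,
    snp: SnpSpec,
    config: SimulationConfig,
    n_reads: int = 1000,
    maternal_fraction: float = 0.5,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Unconverted cDNA amplicon reads over the SNP (expression phasing).

    No bisulfite chemistry: reads are the amplicon reference with the
    haplotype allele at the SNP, plus uniform sequencing errors.
    """
    rng = np.random.default_rng((config.seed, 404))
    ref_arr = np.frombuffer(amplicon.reference.encode("ascii"), dtype=np.uint8).copy()
    n = ref_arr.size
    allele_by_hap = {
        "maternal": _B[snp.maternal_allele],
        "paternal": _B[snp.paternal_allele],
    }
    reads: list[tuple[str, str]] = []
    read_truth: dict[str, str] = {}
    for i in range(n_reads):
        hap = "maternal" if rng.random() < maternal_fraction else "paternal"
        arr = ref_arr.copy()
        arr[amplicon.snp_offset] = allele_by_hap[hap]
        if config.seq_error_rate > 0:
            err = rng.random(n) < config.seq_error_rate
            if err.any():
                idx = _CODE[arr[err]]
                shift = rng.integers(1, 4, err.sum())
                arr[err] = _BASES[(idx + shift) % 4]
        rid = f"expr_read_{i}"
        reads.append((rid, arr.tobytes().decode("ascii")))
        read_truth[rid] = hap
    return reads, read_truth
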