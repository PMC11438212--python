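import re

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dmrscreen.cgi import CpGIsland
from dmrscreen.core import GenomeSequence, GenomicInterval
from dmrscreen.simulate import SimulationConfig, generate_genome, simulate_coverage

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_dna(rng: np.random.Generator, n: int, p_cg_rich: float = 0.3) -> str:
    """Random DNA assembled from alternating CpG-poor and CpG-rich blocks,
    so tile qualification varies along the sequence."""
    chunks = []
    remaining = n
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    while remaining > 0:
        size = int(min(remaining, rng.integers(200, 1500)))
        if rng.random() < p_cg_rich:
            probs = [0.2, 0.3, 0.3, 0.2]  # ~9% CpG density in expectation
        else:
            probs = [0.35, 0.15, 0.15, 0.35]  # ~2%
        chunk = bases[rng.choice(4, size=size, p=probs)]
        chunks.append(chunk)
        remaining -= size
    return np.concatenate(chunks).tobytes().decode("ascii")


def brute_force_tile_counts(seq: str, tile_bp: int) -> list[int]:
    """Per-full-tile CpG counts by direct string scan (a CpG belongs to the
    tile holding its C; the trailing partial tile is dropped)."""
    counts = []
    for s in range(0, len(seq) - len(seq) % tile_bp, tile_bp):
        chunk = seq[s : s + tile_bp + 1]  # lookahead for a boundary CpG
        counts.append(
            sum(1 for m in re.finditer("CG", chunk) if m.start() < tile_bp)
        )
    return counts


def brute_force_cgis(
    seq: str, tile_bp: int = 1000, min_density_pct: float = 3.0, k: int = 1
) -> list[tuple[int, int, int]]:
    """Independent run-length oracle: (start, end, n_cpg) per island."""
    counts = brute_force_tile_counts(seq, tile_bp)
    qualify = [100.0 * k * c / tile_bp > min_density_pct for c in counts]
    islands = []
    i = 0
    while i < len(qualify):
        if not qualify[i]:
            i += 1
            continue
        j = i
        while j < len(qualify) and qualify[j]:
            j += 1
        if j - i >= 2:
            islands.append(
                (i * tile_bp, j * tile_bp, sum(counts[i:j]))
            )
        i = j
    return islands


def make_island(
    contig="c1",
    start=0,
    end=2000,
    n_cpg=96,
    density_pct=4.8,
    tile_bp=1000,
    cpg_positions=(),
) -> CpGIsland:
    return CpGIsland(
        interval=GenomicInterval(contig, start, end),
        tile_count=(end - start) // tile_bp,
        n_cpg=n_cpg,
        density_pct=density_pct,
        cpg_positions=tuple(cpg_positions),
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default simulation shared by read-only tests."""
    config = SimulationConfig(seed=7)
    genomes, genes, truth = generate_genome(config)
    sites = simulate_coverage(genomes, truth, config)
    return config, genomes, genes, truth, sites


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def short_genome():
    # 3 kb: CG-dense first two tiles, empty third tile
    tile = "CG" + "AT" * 9  # 1 CpG per 20 bp -> 5% density per 1 kb tile
    dense = tile * 100  # 2000 bp, 100 CpGs
    return GenomeSequence("c1", dense + "A" * 1000)
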