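"""CpG-island detection and windowed CpG-density tracks.

A contig is tiled into consecutive non-overlapping tiles (default 1 kb)
anchored at position 0.  A tile qualifies when its CpG density is strictly
above the threshold (default 3%), and a CpG island is a maximal run of at
least two adjacent qualifying tiles, merged into one interval.  An isolated
qualifying tile is not an island, and the trailing partial tile never
qualifies.

Density convention: ``density_pct = 100 * k * n_cpg / length`` with the
multiplier ``k`` configurable (default 1: CpG dinucleotides per bp, as a
percent).  Under k=1 a 2 kb island needs 96 CpGs to clear 4.75% density,
which keeps the downstream ">95 CpG sites" and ">4% CpG content" candidate
gates mutually consistent.

Megabase windows exist purely to allow parallel computation; detection over
windows merges boundary tiles in a reduce step and is exactly equivalent to
detection over the whole contig.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenomeSequence, GenomicInterval, cpg_positions

DEFAULT_TILE_BP = 1000
DEFAULT_MIN_DENSITY_PCT = 3.0
DEFAULT_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class Tile:
    """One fixed-length tile with its CpG count and density."""

    interval: GenomicInterval
    n_cpg: int
    density_pct: float


@dataclass(frozen=True)
class CpGIsland:
    """Merged run of >=2 adjacent qualifying tiles."""

    interval: GenomicInterval
    tile_count: int
    n_cpg: int
    density_pct: float
    cpg_positions: tuple[int, ...]

    @property
    def contig_id(self) -> str:
        return self.interval.contig_id

    @property
    def name(self) -> str:
        return f"{self.interval.contig_id}:{self.interval.start}-{self.interval.end}"


@dataclass(frozen=True)
class DensityTrack:
    """Per-window CpG density (percent) along one contig."""

    contig_id: str
    window_bp: int
    contig_length: int
    values: tuple[float, ...]


def partition_windows(
    genomes: list[GenomeSequence] | GenomeSequence,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[GenomicInterval]:
    """Consecutive non-overlapping windows covering each contig.

    The final window of a contig may be shorter.  Windowing is a
    parallelization device only: per-window computation composed with the
    boundary merge is identical to unwindowed computation.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if isinstance(genomes, GenomeSequence):
        genomes = [genomes]
    out = []
    for g in genomes:
        n = len(g)
        for start in range(0, n, window_bp):
            out.append(GenomicInterval(g.contig_id, start, min(start + window_bp, n)))
    return out


def compute_density_track(
    seq: GenomeSequence,
    window_bp: int,
    density_multiplier: int = 1,
) -> DensityTrack:
    """CpG density per consecutive window, as percent.

    A CpG belongs to the window containing its forward-strand C.  The
    trailing partial window is normalized by its actual length.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    n = len(seq)
    n_windows = -(-n // window_bp)  # ceil
    pos = cpg_positions(seq.sequence)
    counts = np.bincount(pos // window_bp, minlength=n_windows).astype(float)
    lengths = np.full(n_windows, window_bp, dtype=float)
    if n % window_bp:
        lengths[-1] = n % window_bp
    values = 100.0 * density_multiplier * counts / lengths
    return DensityTrack(seq.contig_id, window_bp, n, tuple(values.tolist()))


def _tile_qualification(
    pos: np.ndarray,
    contig_len: int,
    tile_bp: int,
    min_density_pct: float,
    density_multiplier: int,
) -> tuple[np.ndarray, np.ndarray]:
    """(per-full-tile CpG counts, strict-threshold qualification mask)."""
    n_full = contig_len // tile_bp
    if n_full == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    counts = np.bincount(
        pos[pos < n_full * tile_bp] // tile_bp, minlength=n_full
    ).astype(np.int64)
    density = 100.0 * density_multiplier * counts / tile_bp
    return counts, density > min_density_pct


def _merge_runs(
    qualify: np.ndarray,
    counts: np.ndarray,
    pos: np.ndarray,
    contig_id: str,
    tile_bp: int,
    density_multiplier: int,
    min_tiles: int = 2,
) -> list[CpGIsland]:
    """Merge maximal runs of >=min_tiles qualifying tiles into islands."""
    islands: list[CpGIsland] = []
    if qualify.size == 0:
        return islands
    # run boundaries on the padded qualification mask
    padded = np.concatenate(([False], qualify, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for t0, t1 in zip(starts, ends):
        if t1 - t0 < min_tiles:
            continue
        start, end = int(t0) * tile_bp, int(t1) * tile_bp
        n_cpg = int(counts[t0:t1].sum())
        in_island = pos[(pos >= start) & (pos < end)]
        islands.append(
            CpGIsland(
                interval=GenomicInterval(contig_id, start, end),
                tile_count=int(t1 - t0),
                n_cpg=n_cpg,
                density_pct=100.0 * density_multiplier * n_cpg / (end - start),
                cpg_positions=tuple(int(p) for p in in_island),
            )
        )
    return islands


def detect_cgis(
    seq: GenomeSequence,
    tile_bp: int = DEFAULT_TILE_BP,
    min_density_pct: float = DEFAULT_MIN_DENSITY_PCT,
    density_multiplier: int = 1,
) -> list[CpGIsland]:
    """Detect CpG islands on one contig, sorted by start.

    Contigs shorter than two tiles yield no islands.
    """
    if tile_bp <= 0:
        raise ValueError("tile_bp must be positive")
    if min_density_pct < 0:
        raise ValueError("min_density_pct must be >= 0")
    pos = cpg_positions(seq.sequence)
    counts, qualify = _tile_qualification(
        pos, len(seq), tile_bp, min_density_pct, density_multiplier
    )
    return _merge_runs(qualify, counts, pos, seq.contig_id, tile_bp, density_multiplier)


def detect_cgis_windowed(
    seq: GenomeSequence,
    tile_bp: int = DEFAULT_TILE_BP,
    min_density_pct: float = DEFAULT_MIN_DENSITY_PCT,
    density_multiplier: int = 1,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[CpGIsland]:
    """Window-parallel CGI detection, exactly equivalent to :func:`detect_cgis`.

    The map step evaluates tile qualification inside each window (with a
    1 bp lookahead so a CpG straddling the window edge is still seen); the
    reduce step concatenates the per-window masks and merges runs across
    window boundaries.  Requires window_bp to be a multiple of tile_bp so
    the window grid respects the tile grid.
    """
    if window_bp % tile_bp != 0:
        raise ValueError("window_bp must be a multiple of tile_bp")
    n = len(seq)
    all_counts = []
    all_pos = []
    for w in partition_windows(seq, window_bp):
        # lookahead of 1 bp catches a CpG whose G falls in the next window
        chunk = seq.sequence[w.start : min(w.end + 1, n)]
        local = cpg_positions(chunk)
        local = local[local < (w.end - w.start)]
        all_pos.append(local + w.start)
        n_full_local = (w.end - w.start) // tile_bp
        counts = np.bincount(
            local[local < n_full_local * tile_bp] // tile_bp,
            minlength=n_full_local,
        ).astype(np.int64)
        all_counts.append(counts)
    pos = np.concatenate(all_pos) if all_pos else np.empty(0, dtype=np.int64)
    counts = (
        np.concatenate(all_counts) if all_counts else np.empty(0, dtype=np.int64)
    )
    # the global trailing partial tile was already excluded by the last
    # window's n_full_local; earlier windows are multiples of tile_bp
    density = 100.0 * density_multiplier * counts / tile_bp
    qualify = density > min_density_pct
    return _merge_runs(qualify, counts, pos, seq.contig_id, tile_bp, density_multiplier)
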