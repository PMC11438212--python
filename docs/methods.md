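# Methods

## CpG-island model

A CpG dinucleotide is identified by the forward-strand position of its C;
the reverse-strand CpG at the same locus is the same biological site.
`N` and IUPAC ambiguity codes never form part of a CpG, which biases
density conservatively low in gappy assemblies.

Islands are defined operationally, not by the Gardiner-Garden or
Takai-Jones criteria: contigs are tiled into consecutive non-overlapping
tiles of `tile_bp` (default 1000) anchored at position 0, a tile qualifies
when its CpG density is strictly above `min_density_pct` (default 3), and
an island is a maximal run of at least two adjacent qualifying tiles.
Consequences that are deliberate and tested: an isolated qualifying tile
is not an island; the trailing partial tile never qualifies; island
boundaries are tile-grid-aligned, so island length is always a multiple of
the tile size.

Density convention: `density_pct = 100 · k · n_CpG / length` with
`density_multiplier` k = 1 by default, i.e. CpG dinucleotides per bp as a
percent. k = 1 keeps the candidate gates mutually consistent (a 2 kb
island needs 96 CpGs for > 4.75% density, which also clears the "> 95
sites" gate); k = 2 (counting both bases of the dinucleotide) is retained
as an option because both conventions circulate in the literature.

Megabase windows (`partition_windows`, `detect_cgis_windowed`) exist only
to allow parallel computation. The map step evaluates tile qualification
per window with a 1 bp lookahead (so a CpG whose C is the window's last
base is still seen); the reduce step concatenates qualification masks and
merges runs across window boundaries. The windowed path is exactly
equivalent to the unwindowed one — a tested invariant — which requires the
window size to be a multiple of the tile size.

## Methylation summaries and classification

Per-CpG counts enter in the Bismark coverage dialect (6 columns, 1-based)
or a 0-based variant; the percent column is always recomputed from the
counts. Where an extractor emits separate top-/bottom-strand records,
`collapse_strands` folds the bottom-strand (G-position) record onto the
forward-strand C using the genome.

Each covered island gets two percent-methylation estimates: the unweighted
mean of per-site percents (the default basis everywhere downstream, since
the screen averages "over the CpG sites") and the read-weighted percent
`100·Σmeth/Σ(meth+unmeth)`. Both are reported; the choice is a config
switch (`basis`) because deeply covered sites dominate the weighted
estimate while the site mean treats sites equally. The spread statistic is
the *population* SD of per-site percents — the covered sites are the whole
population of interest, and the population SD of values bounded in
[0, 100] is itself bounded by 50, which makes the < 25 gate interpretable
as "less than half the maximal possible spread". Percent vectors are
sorted before reduction so summaries are bit-identical under input
reordering. Classification thresholds are strict: > 80% highly
methylated, < 20% highly unmethylated, boundary values intermediate.

## Candidate gates

Defaults: methylation mean in [45, 55] (inclusive — a stated range, not an
"over"), site SD < 25 (strict), total read observations > 400 (strict),
covered CpG sites > 95 (strict), island CpG density > 4% (strict).
"Read observations" means the sum of per-site call counts, the only read
quantity derivable from a coverage file. The sites gate counts *covered*
sites rather than all island CpGs: the gate exists to guarantee
well-estimated statistics, and uncovered sites contribute nothing to them.
All thresholds are fields of `FilterCriteria` so the screen can be
re-tuned for other species or depths; monotonicity (tightening any one
threshold shrinks the candidate set) is property-tested.

## Gene association

Six strand-aware positional relations, evaluated for every same-contig
island/feature pair. When several hold, one is reported by priority
within > spans > starts_inside > ends_inside > near_start > near_end
(`all_relations=True` disables the collapse). Flank geometry: near_start
means the island lies on the 5′ side of the feature's start with a gap of
at most `flank_bp` (5000), near_end symmetrically on the 3′ side of the
end; a gap of zero (abutting) counts, overlap is handled exclusively by
the overlap relations. A strand-naive mode treats every feature as
forward.

## Allele phasing

A trio SNP is informative iff the mother is homozygous X/X and the
offspring heterozygous X/Y; then maternal = X, paternal = Y. A
heterozygous mother still yields the offspring's two alleles with unknown
parental assignment, which the expression caller reports as
`monoallelic_unknown_parent` when skewed.

Bisulfite chemistry is folded into read splitting: on forward-strand
converted reads every unmethylated C reads as T, so a non-CpG C allele is
*expected* to read T and is matched as such. Two alleles whose expected
bases collide (C/T on forward reads, G/A on reverse) raise
`ConfoundedSnpError` up front instead of silently misassigning reads —
correctness over coverage; opposite-strand rescue is out of scope.

CpG calling is per anchored read/clone at exact offsets (amplicons are
short and fixed; no indel alignment): C = methylated, T = unmethylated,
anything else no-call. Reference Cs outside CpGs and the SNP must all read
T after full conversion; the fraction still read as C estimates the
conversion-failure rate per read, pooled across reads for the assay-level
estimate. QC fails a read when that estimate exceeds 5%, the no-call
fraction exceeds 20%, or mismatches outside CpG/SNP/convertible positions
exceed 10% — all configurable. Clone mode shares the caller; clones are
expected vector-trimmed, and the QUMA-style clone-by-site lollipop matrix
is emitted as TSV.

Expression calls use thresholds this package defines (no published rule
exists for the motivating assays): monoallelic when the major allele's
fraction ≥ 0.85, biallelic when both fractions lie in [0.35, 0.65],
ambiguous otherwise, insufficient-coverage below 20 informative reads.
They are reported alongside the raw fractions, never instead of them.

## Synthetic methylome

What it emulates: a CpG-depleted background (default 1% CpG density,
fully methylated, as in vertebrate bulk genomes) with planted tile-aligned
islands of exact density — island CpGs sit on an even lattice, so the
planted density is exact rather than approximate and density-gate tests
are sharp. States: methylated, unmethylated, imprinted (either parent),
or noisy(p). One synthetic gene per island with the island at the gene
start (or 1 kb upstream in `near_start` geometry). A planted SNP sits
mid-island in a lattice gap, at least 2 bp from any assayed CpG, with
neighbours adjusted so neither allele can create a CpG; the reference
sequence carries the maternal allele. Background contigs are rejected and
resampled (bounded retries) if random background alone would form two
adjacent qualifying tiles, so zero-island genomes contain no detectable
island.

Coverage: per-site total reads ~ Poisson(depth), split Binomial(·, ½)
between alleles; a read reports methylated with probability
`p·(1−e) + (1−p)·((1−c)(1−e) + c·e)` for true allele methylation p,
conversion rate c and error rate e — methylation protects the C, failed
conversion or a miscall on a converted T produces a false methylated
call. Amplicon reads apply the same chemistry base-by-base along the two
haplotypes, including converting an unmethylated C *allele* at the SNP
(the reason C/T SNPs are unusable); expression reads skip conversion.

Defaults are the study conditions throughout: depth 30 reads/CpG (typical
single-sample WGBS), conversion rate 0.99, sequencing error 0.001, three
2 kb islands at 4.8% density (96 CpGs — the smallest island that can clear
the sites and density gates) on a 60 kb contig, one of each methylation
class, the imprinted one carrying an informative A/G SNP.

What the simulator does not model — hence what passing tests do not show
about real data: fragment-level read simulation (mapping bias, PCR
duplicates, coverage autocorrelation), CHG/CHH methylation, partially
methylated domains and intermediate biological methylation within an
allele, cell-type mixtures that blur the 50% signature, SNP ascertainment,
and assembly gaps. Recovery results on this generator demonstrate the
pipeline's correctness and its behaviour under binomial sampling noise,
not screening power on real methylomes.

## Numerical choices and degenerate inputs

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive)
and coverage (1-based) convert at the I/O boundary only. Uncovered islands
are flagged, never raised, and excluded from gating and scatter output;
classification or gating an uncovered summary raises. Zero-coverage
coverage rows are dropped on read; a percent column disagreeing with
counts by more than 0.5 points warns and the counts win. Candidate tables
sort by |mean − 50| ascending, ties by total reads descending, with a
stable sort. Random number use is seeded everywhere; simulator streams
derive from (seed, stage-tag) tuples so stages are independently
reproducible and a given config+seed is byte-identical across runs.

## Problem sizes

The test suite and acceptance script run at desk scale by choice of
simulation size: 60 kb contigs with three 2 kb islands, depth 30 (gate
recovery, 50 seeds), 200-read amplicons (phasing, 100 seeds), 100 kb
random sequences for detector-oracle equivalence (100 replicates), and a
2.3 Mb contig for the megabase-windowing equivalence check. Statistical
assertions use 3-standard-error bands around the binomial expectations.
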