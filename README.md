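# dmrscreen

Screening candidate imprinted differentially methylated regions (DMRs)
from whole-genome bisulfite sequencing (WGBS), with allele-specific
methylation and expression phasing — plus a synthetic diploid methylome
generator so the whole pipeline is testable without any external data.

## The problem

Genomic imprinting silences one parental allele of a gene, usually through
a germline-established DMR: a CpG island (CGI) methylated on exactly one
parental allele. In bulk WGBS such a region has a distinctive signature —
roughly half the reads methylated at *every* CpG site — which separates it
from ordinary fully methylated (~100%) or unmethylated (~0%) islands.
`dmrscreen` implements that screen for genomes where imprinting maps are
incomplete (the motivating use case is marsupial genomes with a single
brain methylome), followed by the assays used to confirm a candidate:
SNP-based partitioning of bisulfite amplicon reads or Sanger clones into
parental alleles, per-CpG methylation calling with bisulfite-conversion
QC, and allele-specific expression counting from cDNA amplicons.

## The method

1. **CGI detection.** Each contig is tiled into non-overlapping 1 kb tiles;
   a tile qualifies when its CpG density `100·n_CpG/L` exceeds 3%
   (strictly), and a CGI is a maximal run of ≥ 2 adjacent qualifying tiles.
   Megabase windows are supported as a pure parallelization device and are
   provably equivalent to unwindowed detection.
2. **Methylation summary.** Per-CpG counts (Bismark-coverage dialect) are
   mapped into each CGI; the summary keeps the unweighted mean of per-site
   percent methylation m̄, the read-weighted percent, the cross-site
   population SD σ, total read observations and covered-site count.
   Islands classify as highly methylated (> 80%), highly unmethylated
   (< 20%) or intermediate.
3. **Gene association.** Each CGI is related to annotated genes by six
   positional relations (within / starts inside / ends inside / spans /
   within 5 kb of the 5′ start / within 5 kb downstream of the 3′ end),
   strand-aware.
4. **Candidate gates.** A CGI is a candidate DMR when
   45 ≤ m̄ ≤ 55, σ < 25, reads > 400, covered CpG sites > 95 and CpG
   density > 4% — the half-methylated, low-spread, well-measured signature.
5. **Allele phasing.** A SNP where the mother is homozygous and the
   offspring heterozygous assigns the offspring's alleles to parents;
   bisulfite amplicon reads are partitioned by the bisulfite-*expected*
   base at the SNP (C/T and reverse-strand G/A SNPs are rejected as
   confounded), CpGs are called per read (C = methylated, T =
   unmethylated) with conversion-failure QC from non-CpG cytosines, and
   per-parent methylation is tallied. The expression path counts
   unconverted cDNA reads per allele and calls monoallelic/biallelic.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (bulky intermediates go to `scratch/`, tables to `results/`):

```bash
python analysis/01_simulate_methylome.py --seed 1
python analysis/02_screen_candidates.py
python analysis/03_phase_alleles.py
```

At seed 1 this prints:

```
detected 3 CpG islands, 3 with coverage, 1 candidate DMR(s)
classification of covered CGIs: {'highly_methylated': 1, 'highly_unmethylated': 1, 'intermediate': 1}
planted imprinted islands recovered as candidates: 1/1; false candidates: 0
top candidate: contig_0:21000-23000 mean 49.5% site-SD 9.9% reads 2873 sites 96 -> gene_1 (near_end)
```

The simulation planted three 2 kb islands (96 CpGs, 4.8% density) —
fully methylated, unmethylated, and maternally methylated with a linked
A/G SNP. Only the imprinted island passes the gates: its mean methylation
sits at 49.5% with a per-site SD of 9.9%, inside the 45–55 / < 25 gate
box, while the other two classify as highly methylated/unmethylated and
fail the methylation-range gate. Phasing the 200 amplicon reads then
separates the alleles cleanly:

```
allele-specific methylation over 14 CpG sites:
  maternal 99.9% (106 reads), paternal 1.0% (94 reads), 0 unassigned
  pooled bisulfite conversion-failure estimate: 1.00%
expression, biallelic_locus: maternal 50.1% / paternal 49.9% (1250 reads) -> biallelic
expression, paternally_expressed_locus: maternal 0.1% / paternal 100.0% (2000 reads) -> monoallelic_paternal
```

The maternal allele reads ~99.9% methylated (methylated cytosines are
protected from conversion) and the paternal ~1.0% — the residue of the
simulated 99% conversion rate, which the QC estimator recovers exactly.

The same stages are available as a CLI (`dmrscreen simulate / detect-cgi /
screen / phase-meth / phase-expr`), each writing a run manifest with input
checksums and per-stage counts.

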