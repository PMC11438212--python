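#!/usr/bin/env python
"""Simulate the synthetic diploid methylome used by the rest of the analysis.

Generates a genome with three planted CpG islands (one methylated on both
alleles, one unmethylated, one maternally methylated with a linked A/G
SNP), one synthetic gene per island, whole-genome per-CpG bisulfite
coverage at 30x, and 200 bisulfite amplicon reads over the imprinted
island's SNP.  Bulky data files go to scratch/simulated/; a small truth
table summarising what was planted goes to results/.

Usage: python analysis/01_simulate_methylome.py [--seed N]
"""

import argparse
from pathlib import Path

import pandas as pd

from dmrscreen.io import write_amplicon_json, write_coverage, write_fasta, write_fastq, write_gff
from dmrscreen.simulate import (
    SimulationConfig,
    generate_genome,
    simulate_amplicon_reads,
    simulate_coverage,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    outdir = ROOT / "scratch" / "simulated"
    outdir.mkdir(parents=True, exist_ok=True)
    resdir = ROOT / "results"
    resdir.mkdir(exist_ok=True)

    config = SimulationConfig(seed=args.seed)
    genomes, genes, truth = generate_genome(config)
    sites = simulate_coverage(genomes, truth, config)
    reads, amplicon, snp, _ = simulate_amplicon_reads(
        genomes, truth, config, "island_2", n_reads=200
    )

    write_fasta(outdir / "genome.fa", genomes)
    write_gff(outdir / "genes.gff3", genes)
    write_coverage(outdir / "coverage.tsv", sites)
    write_fastq(outdir / "amplicon_reads.fastq", reads)
    write_amplicon_json(outdir / "amplicon.json", amplicon, snp)
    truth.to_json(outdir / "truth.json")

    table = pd.DataFrame(
        [
            {
                "island_id": i.island_id,
                "contig": i.contig_id,
                "start": i.start,
                "end": i.end,
                "state": i.state,
                "n_cpg": i.n_cpg,
                "density_pct": round(i.density_pct, 3),
                "snp": "" if i.snp is None else
                       f"{i.snp['maternal_allele']}/{i.snp['paternal_allele']}"
                       f"@{i.snp['pos']}",
            }
            for i in truth.islands
        ]
    )
    table.to_csv(resdir / "01_simulation_truth.tsv", sep="\t", index=False)

    print(f"simulated {len(genomes)} contig(s) of "
          f"{config.contig_length_bp:,} bp at seed {config.seed}")
    print(f"planted islands:\n{table.to_string(index=False)}")
    print(f"{len(sites)} covered CpG sites at ~{config.depth:.0f}x; "
          f"{len(reads)} amplicon reads over the imprinted island's SNP")
    print(f"data under {outdir}, truth table at results/01_simulation_truth.tsv")


if __name__ == "__main__":
    main()
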