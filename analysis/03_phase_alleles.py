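#!/usr/bin/env python
"""Parent-of-origin analysis of the candidate DMR and linked expression.

Takes the amplicon reads simulated over the imprinted island's SNP,
infers the informative SNP from mother/offspring genotypes (mother A/A,
offspring A/G), partitions reads by allele, calls per-CpG methylation with
conversion QC, and tallies per-parent methylation — the allele-specific
methylation assay.  Then simulates unconverted cDNA reads for a biallelic
and a paternally monoallelic expression scenario at the same SNP and
applies the expression caller.

Usage: python analysis/03_phase_alleles.py   (after 01)
"""

from pathlib import Path

import pandas as pd

from dmrscreen.io import read_amplicon_json, read_fastq
from dmrscreen.phasing import (
    count_allele_expression,
    estimate_conversion_failure,
    infer_parental_alleles,
    lollipop_matrix,
    per_allele_methylation,
    split_reads_by_allele,
)
from dmrscreen.simulate import SimulationConfig, simulate_expression_reads

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    datadir = ROOT / "scratch" / "simulated"
    if not datadir.exists():
        raise SystemExit("run analysis/01_simulate_methylome.py first")
    resdir = ROOT / "results"

    amplicon, planted_snp = read_amplicon_json(datadir / "amplicon.json")
    # trio genotyping: homozygous mother, heterozygous offspring
    snp = infer_parental_alleles(
        (planted_snp.maternal_allele, planted_snp.maternal_allele),
        (planted_snp.maternal_allele, planted_snp.paternal_allele),
        contig_id=amplicon.contig_id,
        pos=planted_snp.pos,
    )
    reads = read_fastq(datadir / "amplicon_reads.fastq")
    partition = split_reads_by_allele(reads, amplicon, snp)
    result, calls = per_allele_methylation(partition, amplicon)
    conv_fail = estimate_conversion_failure(
        calls["maternal"] + calls["paternal"]
    )

    meth_table = pd.DataFrame(
        [
            {"parent": "maternal", "n_reads": result.n_maternal,
             "percent_meth": result.maternal_pct},
            {"parent": "paternal", "n_reads": result.n_paternal,
             "percent_meth": result.paternal_pct},
            {"parent": "unassigned", "n_reads": result.n_unassigned,
             "percent_meth": None},
        ]
    )
    meth_table.to_csv(resdir / "03_allelic_methylation.tsv", sep="\t",
                      index=False)
    lollipop_matrix(calls, amplicon).to_csv(resdir / "03_lollipop.tsv",
                                            sep="\t")

    print(f"informative SNP {snp.maternal_allele}/{snp.paternal_allele} "
          f"at {snp.contig_id}:{snp.pos} (maternal/paternal)")
    print(f"allele-specific methylation over {len(amplicon.cpg_offsets)} "
          f"CpG sites:")
    print(f"  maternal {result.maternal_pct:.1f}% ({result.n_maternal} reads), "
          f"paternal {result.paternal_pct:.1f}% ({result.n_paternal} reads), "
          f"{result.n_unassigned} unassigned")
    print(f"  pooled bisulfite conversion-failure estimate: {conv_fail:.2%}")

    # allele-specific expression at the same SNP
    config = SimulationConfig(seed=99, seq_error_rate=0.001)
    rows = []
    for label, frac, n in [("biallelic_locus", 0.5, 1250),
                           ("paternally_expressed_locus", 0.0, 2000)]:
        expr_reads, _ = simulate_expression_reads(
            amplicon, snp, config, n_reads=n, maternal_fraction=frac
        )
        r = count_allele_expression(expr_reads, amplicon.snp_offset, snp)
        rows.append({"scenario": label,
                     "count_maternal": r.count_maternal,
                     "count_paternal": r.count_paternal,
                     "maternal_pct": 100 * r.maternal_fraction,
                     "paternal_pct": 100 * r.paternal_fraction,
                     "call": r.call})
        print(f"expression, {label}: maternal "
              f"{100 * r.maternal_fraction:.1f}% / paternal "
              f"{100 * r.paternal_fraction:.1f}% "
              f"({r.count_maternal + r.count_paternal} reads) -> {r.call}")
    pd.DataFrame(rows).to_csv(resdir / "03_allelic_expression.tsv", sep="\t",
                              index=False)
    print("tables: results/03_allelic_methylation.tsv, 03_lollipop.tsv, "
          "03_allelic_expression.tsv")


if __name__ == "__main__":
    main()
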