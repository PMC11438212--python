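#!/usr/bin/env python
"""Screen the simulated methylome for candidate imprinted DMRs.

Reads the files written by 01_simulate_methylome.py back through the
package's own parsers (exercising the file dialects end to end), then runs
the full screen: CpG-island detection (1 kb tiles, >3% CpG density, >=2
adjacent tiles), per-island methylation summaries, gene association, and
the stringent candidate gates (45-55% methylation, site SD < 25%, > 400
reads, > 95 CpG sites, > 4% density).  Writes the summary, candidate and
scatter tables to results/ and reports what was found.

Usage: python analysis/02_screen_candidates.py   (after 01)
"""

from pathlib import Path

from dmrscreen.io import read_coverage, read_fasta, read_gff
from dmrscreen.screen import run_screen
from dmrscreen.simulate import TruthTable

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    datadir = ROOT / "scratch" / "simulated"
    if not datadir.exists():
        raise SystemExit("run analysis/01_simulate_methylome.py first")
    resdir = ROOT / "results"

    genomes = read_fasta(datadir / "genome.fa")
    genes = read_gff(datadir / "genes.gff3")
    sites = read_coverage(datadir / "coverage.tsv")
    truth = TruthTable.from_json(datadir / "truth.json")

    result = run_screen(genomes, genes, sites)
    result.summary_table.to_csv(resdir / "02_cgi_summary.tsv", sep="\t",
                                index=False)
    result.candidate_table.to_csv(resdir / "02_candidates.tsv", sep="\t",
                                  index=False)
    result.scatter_table.to_csv(resdir / "02_scatter.tsv", sep="\t",
                                index=False)

    counts = result.stage_counts
    print(f"detected {counts['cgis_detected']} CpG islands, "
          f"{counts['cgis_covered']} with coverage, "
          f"{counts['candidates']} candidate DMR(s)")
    classes = result.scatter_table["class"].value_counts().to_dict()
    print(f"classification of covered CGIs: {classes}")

    planted_imprinted = {
        (i.contig_id, i.start, i.end)
        for i in truth.islands if i.state.startswith("imprinted")
    }
    called = {
        (c.summary.island.interval.contig_id,
         c.summary.island.interval.start,
         c.summary.island.interval.end)
        for c in result.candidates if c.is_candidate
    }
    hit = planted_imprinted & called
    print(f"planted imprinted islands recovered as candidates: "
          f"{len(hit)}/{len(planted_imprinted)}; "
          f"false candidates: {len(called - planted_imprinted)}")
    if not result.candidate_table.empty:
        row = result.candidate_table.iloc[0]
        print(f"top candidate: {row.island} mean {row.mean_pct:.1f}% "
              f"site-SD {row.std_pct:.1f}% reads {row.total_reads} "
              f"sites {row.n_sites_covered} -> {row.feature_id} "
              f"({row.relation})")
    print("tables: results/02_cgi_summary.tsv, 02_candidates.tsv, 02_scatter.tsv")


if __name__ == "__main__":
    main()
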