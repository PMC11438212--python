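"""Synthetic methylome generator: determinism, exactness, self-consistency."""

import numpy as np
import pytest

from dmrscreen.cgi import detect_cgis
from dmrscreen.core import cpg_positions
from dmrscreen.phasing import split_reads_by_allele
from dmrscreen.simulate import (
    ConfigError,
    IslandSpec,
    SimulationConfig,
    SnpPlan,
    TruthTable,
    generate_genome,
    simulate_amplicon_reads,
    simulate_coverage,
    simulate_expression_reads,
    build_amplicon,
)


class TestGenerateGenome:
    def test_same_seed_byte_identical(self):
        a, _, _ = generate_genome(SimulationConfig(seed=3))
        b, _, _ = generate_genome(SimulationConfig(seed=3))
        assert [g.sequence for g in a] == [g.sequence for g in b]

    def test_different_seeds_differ(self):
        a, _, _ = generate_genome(SimulationConfig(seed=3))
        b, _, _ = generate_genome(SimulationConfig(seed=4))
        assert a[0].sequence != b[0].sequence

    def test_island_density_exact(self):
        config = SimulationConfig(seed=5)
        genomes, _, truth = generate_genome(config)
        seq = genomes[0].sequence
        for isl in truth.islands:
            sub = seq[isl.start : isl.end + 1]
            n = sum(
                1 for p in cpg_positions(sub).tolist() if p < isl.end - isl.start
            )
            assert n == isl.n_cpg
            spec_density = 100.0 * n / (isl.end - isl.start)
            assert abs(spec_density - 4.8) <= 0.25

    def test_four_kb_island_at_typical_promoter_density(self):
        # a 4 kb island at 4.7% density carries exactly 188 CpGs
        config = SimulationConfig(
            seed=6,
            islands=[IslandSpec(length_bp=4000, density_pct=4.7,
                                state="imprinted_maternal_methylated")],
        )
        _, _, truth = generate_genome(config)
        assert truth.islands[0].n_cpg == 188

    def test_background_density_within_relative_tolerance(self):
        config = SimulationConfig(seed=8, islands=[])
        genomes, _, truth = generate_genome(config)
        n = len(cpg_positions(genomes[0].sequence))
        expected = config.background_cpg_density_pct / 100 * config.contig_length_bp
        assert abs(n - expected) / expected <= 0.2

    def test_zero_island_background_has_no_detectable_island(self):
        for seed in range(10):
            config = SimulationConfig(seed=seed, islands=[])
            genomes, _, truth = generate_genome(config)
            assert detect_cgis(genomes[0]) == []

    def test_planted_islands_detected_exactly(self):
        for seed in range(10):
            config = SimulationConfig(seed=seed)
            genomes, _, truth = generate_genome(config)
            detected = detect_cgis(genomes[0])
            got = [(i.interval.start, i.interval.end) for i in detected]
            planted = [(i.start, i.end) for i in truth.islands]
            assert got == planted

    def test_gene_geometry_within(self):
        from dmrscreen.association import WITHIN, associate

        config = SimulationConfig(seed=5)
        genomes, genes, truth = generate_genome(config)
        islands = detect_cgis(genomes[0])
        anns = associate(islands, genes)
        for idx, isl in enumerate(truth.islands):
            rels = [a.relation for a in anns
                    if a.island.interval.start == isl.start
                    and a.feature_id == f"gene_{idx}"]
            assert rels == [WITHIN]

    def test_gene_geometry_near_start(self):
        from dmrscreen.association import NEAR_START, associate

        config = SimulationConfig(seed=5, gene_geometry="near_start",
                                  contig_length_bp=80_000)
        genomes, genes, truth = generate_genome(config)
        islands = detect_cgis(genomes[0])
        anns = associate(islands, genes)
        for idx, isl in enumerate(truth.islands):
            rel = [a.relation for a in anns
                   if a.island.interval.start == isl.start
                   and a.feature_id == f"gene_{idx}"]
            assert rel == [NEAR_START]

    def test_islands_must_fit(self):
        with pytest.raises(ConfigError, match="fit"):
            generate_genome(SimulationConfig(seed=1, contig_length_bp=20_000))

    def test_confounded_snp_plan_rejected(self):
        with pytest.raises(ConfigError, match="confounded"):
            SnpPlan(maternal_allele="C", paternal_allele="T")

    def test_truth_round_trip(self, tmp_path, default_sim):
        _, _, _, truth, _ = default_sim
        p = tmp_path / "truth.json"
        truth.to_json(p)
        assert TruthTable.from_json(p) == truth


class TestSimulateCoverage:
    def test_deterministic_given_seed(self):
        config = SimulationConfig(seed=9)
        genomes, _, truth = generate_genome(config)
        a = simulate_coverage(genomes, truth, config)
        b = simulate_coverage(genomes, truth, config)
        assert a == b

    def test_perfect_conversion_unmethylated_island_all_zero(self):
        config = SimulationConfig(seed=10, conversion_rate=1.0, seq_error_rate=0.0)
        genomes, _, truth = generate_genome(config)
        sites = simulate_coverage(genomes, truth, config)
        isl = next(i for i in truth.islands if i.state == "unmethylated")
        in_isl = [s for s in sites if isl.start <= s.pos < isl.end]
        assert in_isl and all(s.count_meth == 0 for s in in_isl)

    def test_conversion_failure_rate_recovered_at_high_depth(self):
        config = SimulationConfig(
            seed=12, depth=10_000, conversion_rate=0.99, seq_error_rate=0.0,
            islands=[IslandSpec(state="unmethylated")],
        )
        genomes, _, truth = generate_genome(config)
        sites = simulate_coverage(genomes, truth, config)
        isl = truth.islands[0]
        in_isl = [s for s in sites if isl.start <= s.pos < isl.end]
        m = sum(s.count_meth for s in in_isl)
        n = sum(s.coverage for s in in_isl)
        p = 0.01
        se = np.sqrt(p * (1 - p) / n)
        assert m / n == pytest.approx(p, abs=3 * se)

    def test_imprinted_site_near_half_at_high_depth(self):
        config = SimulationConfig(
            seed=14, depth=10_000, conversion_rate=1.0, seq_error_rate=0.0,
            islands=[IslandSpec(state="imprinted_maternal_methylated")],
        )
        genomes, _, truth = generate_genome(config)
        sites = simulate_coverage(genomes, truth, config)
        isl = truth.islands[0]
        for s in sites:
            if isl.start <= s.pos < isl.end:
                se = np.sqrt(0.25 / s.coverage)
                assert s.count_meth / s.coverage == pytest.approx(0.5, abs=3 * se)
                break


class TestAmpliconReads:
    def test_deterministic_given_seed(self):
        config = SimulationConfig(seed=15)
        genomes, _, truth = generate_genome(config)
        a, *_ = simulate_amplicon_reads(genomes, truth, config, "island_2", 50)
        b, *_ = simulate_amplicon_reads(genomes, truth, config, "island_2", 50)
        assert a == b

    def test_perfect_conversion_separates_haplotypes_deterministically(self):
        config = SimulationConfig(seed=16, conversion_rate=1.0, seq_error_rate=0.0)
        genomes, _, truth = generate_genome(config)
        reads, amp, snp, read_truth = simulate_amplicon_reads(
            genomes, truth, config, "island_2", 60
        )
        for rid, seq in reads:
            bases = {seq[off] for off in amp.cpg_offsets}
            if read_truth[rid] == "maternal":
                assert bases == {"C"}  # methylated allele fully protected
            else:
                assert bases == {"T"}  # unmethylated allele fully converted

    def test_partition_matches_truth_with_no_error(self):
        config = SimulationConfig(seed=17, conversion_rate=1.0, seq_error_rate=0.0)
        genomes, _, truth = generate_genome(config)
        reads, amp, snp, read_truth = simulate_amplicon_reads(
            genomes, truth, config, "island_2", 100
        )
        part = split_reads_by_allele(reads, amp, snp)
        assert not part["unassigned"]
        for side in ("maternal", "paternal"):
            assert all(read_truth[rid] == side for rid, _ in part[side])

    def test_island_without_snp_rejected(self):
        config = SimulationConfig(seed=18)
        genomes, _, truth = generate_genome(config)
        with pytest.raises(ConfigError, match="SNP"):
            build_amplicon(genomes, truth, "island_0")

    def test_expression_reads_follow_haplotype_fraction(self):
        config = SimulationConfig(seed=19, seq_error_rate=0.0)
        genomes, _, truth = generate_genome(config)
        amp, snp = build_amplicon(genomes, truth, "island_2")
        reads, read_truth = simulate_expression_reads(
            amp, snp, config, n_reads=500, maternal_fraction=0.0
        )
        assert all(h == "paternal" for h in read_truth.values())
        assert all(seq[amp.snp_offset] == snp.paternal_allele
                   for _, seq in reads)
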