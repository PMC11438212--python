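"""Trio genotyping, bisulfite read splitting, QUMA-style calling, expression."""

import pytest

from dmrscreen.phasing import (
    AlignmentError,
    BisulfiteAmplicon,
    ConfoundedSnpError,
    GenotypeInconsistencyError,
    SnpSpec,
    bisulfite_expected_base,
    call_cpg_methylation,
    count_allele_expression,
    estimate_conversion_failure,
    infer_parental_alleles,
    lollipop_matrix,
    per_allele_methylation,
    split_reads_by_allele,
)

# amplicon: CpGs at offsets 2 and 12, SNP at 7, QC (non-CpG C) at 5 and 9
AMP = BisulfiteAmplicon(
    name="amp1",
    reference="TTCGTCTATCTTCGTT",
    contig_id="c1",
    start=100,
    cpg_offsets=(2, 12),
    snp_offset=7,
)


def snp(mat="A", pat="G", informative=True):
    return SnpSpec("c1", 107, mat, pat, informative=informative)


class TestTrioInference:
    def test_informative_homozygous_mother(self):
        s = infer_parental_alleles(("A", "A"), ("A", "G"))
        assert (s.maternal_allele, s.paternal_allele) == ("A", "G")
        assert s.informative

    def test_heterozygous_mother_uninformative_but_keeps_alleles(self):
        s = infer_parental_alleles(("A", "G"), ("A", "G"))
        assert not s.informative
        assert s.reason == "mother_heterozygous"
        assert {s.maternal_allele, s.paternal_allele} == {"A", "G"}

    def test_homozygous_offspring_no_snp(self):
        s = infer_parental_alleles(("A", "A"), ("A", "A"))
        assert not s.informative
        assert s.reason == "no_snp"

    def test_unordered_genotypes(self):
        a = infer_parental_alleles(("T", "T"), ("C", "T"))
        b = infer_parental_alleles(("T", "T"), ("T", "C"))
        assert a == b
        assert (a.maternal_allele, a.paternal_allele) == ("T", "C")

    def test_impossible_offspring_raises(self):
        with pytest.raises(GenotypeInconsistencyError):
            infer_parental_alleles(("A", "A"), ("G", "G"))
        with pytest.raises(GenotypeInconsistencyError):
            infer_parental_alleles(("A", "A"), ("C", "G"))


class TestReadSplitting:
    def make_read(self, base, rid="r"):
        seq = list("TTTGTTTATTTTTGTT")  # fully converted unmethylated read
        seq[7] = base
        return rid, "".join(seq)

    def test_reads_partition_by_snp_base(self):
        reads = [self.make_read("A", "r1"), self.make_read("G", "r2"),
                 self.make_read("C", "r3")]
        part = split_reads_by_allele(reads, AMP, snp())
        assert [r[0] for r in part["maternal"]] == ["r1"]
        assert [r[0] for r in part["paternal"]] == ["r2"]
        assert [r[0] for r in part["unassigned"]] == ["r3"]

    def test_count_conservation(self):
        reads = [self.make_read("ACGT"[i % 4], f"r{i}") for i in range(40)]
        part = split_reads_by_allele(reads, AMP, snp())
        assert sum(len(v) for v in part.values()) == 40

    def test_c_t_snp_is_confounded_on_forward_reads(self):
        with pytest.raises(ConfoundedSnpError):
            split_reads_by_allele([], AMP, snp("C", "T"))

    def test_g_a_snp_is_confounded_on_reverse_reads(self):
        split_reads_by_allele([], AMP, snp("G", "A"))  # fine on forward
        with pytest.raises(ConfoundedSnpError):
            split_reads_by_allele([], AMP, snp("G", "A"), strand="-")

    def test_c_allele_matches_its_converted_t(self):
        # C/A SNP: the C allele is unmethylated non-CpG C and reads T
        part = split_reads_by_allele(
            [self.make_read("T", "rT"), self.make_read("A", "rA")],
            AMP,
            snp("C", "A"),
        )
        assert [r[0] for r in part["maternal"]] == ["rT"]
        assert [r[0] for r in part["paternal"]] == ["rA"]

    def test_short_read_unassigned(self):
        part = split_reads_by_allele([("r", "TTT")], AMP, snp())
        assert [r[0] for r in part["unassigned"]] == ["r"]

    def test_expected_base_logic(self):
        assert bisulfite_expected_base("C", "+") == "T"
        assert bisulfite_expected_base("G", "+") == "G"
        assert bisulfite_expected_base("G", "-") == "A"


class TestCpgCalling:
    def test_fully_converted_unmethylated_clone(self):
        # 23 CpGs all read T -> 0% methylated, 23/23 called
        ref = "AT" + "CG" * 23 + "AT"
        amp = BisulfiteAmplicon("a", ref, "c1", 0,
                                tuple(range(2, 2 + 46, 2)), 49)
        read = "AT" + "TG" * 23 + "AT"
        rc = call_cpg_methylation("clone1", read, amp)
        assert rc.n_meth == 0 and rc.n_unmeth == 23
        assert rc.percent_meth == 0.0

    def test_partial_methylation_percent(self):
        # C at 20 of 23 CpGs -> 87.0%
        ref = "AT" + "CG" * 23 + "AT"
        amp = BisulfiteAmplicon("a", ref, "c1", 0,
                                tuple(range(2, 2 + 46, 2)), 49)
        read = "AT" + "CG" * 20 + "TG" * 3 + "AT"
        rc = call_cpg_methylation("clone2", read, amp)
        assert rc.n_meth == 20
        assert rc.percent_meth == pytest.approx(100 * 20 / 23, abs=0.05)

    def test_conversion_failure_flags_qc(self):
        # 10 non-CpG Cs; one retained C -> 10% conversion failure, over the 5% bar
        ref = "CA" * 10 + "TT"
        amp = BisulfiteAmplicon("a", ref, "c1", 0, (), 21)
        clean = "TA" * 10 + "TT"
        dirty = "CA" + "TA" * 9 + "TT"
        assert call_cpg_methylation("ok", clean, amp).qc_pass
        rc = call_cpg_methylation("bad", dirty, amp)
        assert rc.conversion_failure_est == pytest.approx(0.1)
        assert not rc.qc_pass

    def test_nocall_fraction_flags_qc(self):
        ref = "AT" + "CG" * 5 + "AT"
        amp = BisulfiteAmplicon("a", ref, "c1", 0, tuple(range(2, 12, 2)), 13)
        # 2 of 5 CpGs unreadable -> 40% no-call
        read = "AT" + "NG" * 2 + "CG" * 3 + "AT"
        rc = call_cpg_methylation("r", read, amp)
        assert rc.n_nocall == 2
        assert not rc.qc_pass

    def test_read_longer_than_reference_is_alignment_error(self):
        with pytest.raises(AlignmentError):
            call_cpg_methylation("r", "A" * (len(AMP.reference) + 1), AMP)

    def test_truncated_read_gives_nocalls_beyond_end(self):
        ref = "AT" + "CG" * 5 + "AT"
        amp = BisulfiteAmplicon("a", ref, "c1", 0, tuple(range(2, 12, 2)), 13)
        rc = call_cpg_methylation("r", ref[:6], amp)
        assert rc.n_meth == 2 and rc.n_nocall == 3


class TestPerAlleleMethylation:
    def _amp(self):
        ref = "AT" + "CG" * 3 + "TATT"  # CpGs at 2,4,6; SNP at 9
        return BisulfiteAmplicon("a", ref, "c1", 0, (2, 4, 6), 9)

    def test_planted_imprint_fully_separated(self):
        amp = self._amp()
        mat = [("m" + str(i), "AT" + "CG" * 3 + "TGTT") for i in range(5)]
        pat = [("p" + str(i), "AT" + "TG" * 3 + "TATT") for i in range(5)]
        part = split_reads_by_allele(mat + pat, amp, SnpSpec("c1", 9, "G", "A"))
        result, _ = per_allele_methylation(part, amp)
        assert result.maternal_pct == 100.0
        assert result.paternal_pct == 0.0
        assert result.n_maternal == result.n_paternal == 5

    def test_site_tally_ratio(self):
        # 29 methylated of 30 maternal site-calls -> 96.7%
        amp = self._amp()
        reads = [("m0", "AT" + "TG" + "CG" * 2 + "TGTT")]
        reads += [(f"m{i}", "AT" + "CG" * 3 + "TGTT") for i in range(1, 10)]
        part = {"maternal": reads, "paternal": [], "unassigned": []}
        result, _ = per_allele_methylation(part, amp)
        assert result.maternal_pct == pytest.approx(100 * 29 / 30, abs=0.05)
        assert result.paternal_pct is None
        assert result.n_paternal == 0

    def test_count_conservation_through_pipeline(self, default_sim):
        from dmrscreen.simulate import simulate_amplicon_reads

        config, genomes, genes, truth, _ = default_sim
        reads, amp, s, _ = simulate_amplicon_reads(
            genomes, truth, config, "island_2", n_reads=80
        )
        part = split_reads_by_allele(reads, amp, s)
        result, _ = per_allele_methylation(part, amp)
        assert (
            result.n_maternal + result.n_paternal + result.n_unassigned
            == len(reads)
        )

    def test_lollipop_matrix_shape(self):
        amp = self._amp()
        part = {
            "maternal": [("m0", "AT" + "CG" * 3 + "TGTT")],
            "paternal": [("p0", "AT" + "TG" * 3 + "TATT")],
            "unassigned": [],
        }
        _, calls = per_allele_methylation(part, amp)
        m = lollipop_matrix(calls, amp)
        assert m.shape == (2, 3)
        assert set(m.loc["maternal:m0"]) == {1}
        assert set(m.loc["paternal:p0"]) == {0}

    def test_pooled_conversion_estimator(self):
        ref = "CA" * 10 + "TT"
        amp = BisulfiteAmplicon("a", ref, "c1", 0, (), 21)
        calls = [
            call_cpg_methylation("r1", "TA" * 10 + "TT", amp),
            call_cpg_methylation("r2", "CA" + "TA" * 9 + "TT", amp),
        ]
        assert estimate_conversion_failure(calls) == pytest.approx(1 / 20)


class TestAlleleExpression:
    def reads(self, n_a, n_g, other=0):
        out = [(f"a{i}", "TTA") for i in range(n_a)]
        out += [(f"g{i}", "TTG") for i in range(n_g)]
        out += [(f"x{i}", "TTC") for i in range(other)]
        return out

    def test_balanced_is_biallelic(self):
        r = count_allele_expression(self.reads(625, 625), 2, snp())
        assert r.call == "biallelic"
        assert r.maternal_fraction == pytest.approx(0.5)

    def test_strong_skew_is_monoallelic(self):
        r = count_allele_expression(self.reads(12, 1230), 2, snp())
        assert r.call == "monoallelic_paternal"
        assert r.paternal_fraction == pytest.approx(1230 / 1242, abs=1e-9)

    def test_sixty_forty_still_biallelic(self):
        r = count_allele_expression(self.reads(600, 400), 2, snp())
        assert r.call == "biallelic"

    def test_intermediate_skew_ambiguous(self):
        r = count_allele_expression(self.reads(750, 250), 2, snp())
        assert r.call == "ambiguous"

    def test_uninformative_snp_gives_unknown_parent(self):
        s = infer_parental_alleles(("A", "G"), ("A", "G"))
        r = count_allele_expression(self.reads(990, 10), 2,
                                    SnpSpec("c1", 2, s.maternal_allele,
                                            s.paternal_allele, False))
        assert r.call == "monoallelic_unknown_parent"

    def test_error_mass_reported_separately(self):
        r = count_allele_expression(self.reads(100, 100, other=7), 2, snp())
        assert r.count_other == 7
        assert r.maternal_fraction == pytest.approx(0.5)

    def test_insufficient_coverage(self):
        r = count_allele_expression(self.reads(5, 5), 2, snp())
        assert r.call == "insufficient_coverage"
        assert r.maternal_fraction is None
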