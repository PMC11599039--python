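"""Locus generation: geometry, build registration and sample truth."""

import numpy as np
import pytest

import paraclone as pc
from paraclone.insilico_sanger import _diff_single_gap
from paraclone.locus_forge import LocusConfigError, PsvSpec, ScenarioError


def core_blocks(locus):
    cs = locus.params.core_start
    return (
        locus.gene_seq[cs:cs + locus.core_block_len],
        locus.pseudo_seq[:locus.core_block_len],
    )


class TestBuildLocus:
    def test_core_hamming_equals_psv_count(self, locus):
        g, p = core_blocks(locus)
        diffs = [i for i in range(len(g)) if g[i] != p[i]]
        assert diffs == sorted(s.pseudo_offset for s in locus.psv_sites)

    def test_deterministic_for_seed(self):
        a, b = pc.build_locus(42), pc.build_locus(42)
        assert a.gene_seq == b.gene_seq and a.pseudo_seq == b.pseudo_seq
        assert a.contig() == b.contig()
        assert pc.build_locus(43).gene_seq != a.gene_seq

    def test_zero_psv_preset_gives_identical_cores(self, mini_params):
        import dataclasses
        params = dataclasses.replace(mini_params, psvs=())
        locus = pc.build_locus(3, params)
        g, p = core_blocks(locus)
        assert g == p

    @pytest.mark.parametrize("offset", [-1, 10_000])
    def test_psv_outside_core_rejected(self, mini_params, offset):
        import dataclasses
        bad = dataclasses.replace(
            mini_params, psvs=mini_params.psvs + (PsvSpec(offset, "A", "G", True),)
        )
        with pytest.raises(LocusConfigError, match=str(offset)):
            pc.build_locus(1, bad)

    def test_duplicate_psv_rejected(self, mini_params):
        import dataclasses
        bad = dataclasses.replace(
            mini_params, psvs=mini_params.psvs + (PsvSpec(60, "C", "T", True),)
        )
        with pytest.raises(LocusConfigError, match="duplicate"):
            pc.build_locus(1, bad)

    def test_psv_allele_invariants(self, locus):
        for s in locus.psv_sites:
            assert s.gene_allele != s.pseudo_major_allele
            assert s.buildA_registered == s.pseudo_major_allele
            assert s.buildB_registered in (s.pseudo_major_allele, s.gene_allele)


class TestRenderReference:
    def test_builds_differ_at_exactly_the_discordant_pseudogene_sites(self, locus):
        a = pc.render_reference(locus, "buildA").contig_seq
        b = pc.render_reference(locus, "buildB").contig_seq
        diffs = [i for i in range(len(a)) if a[i] != b[i]]
        expected = sorted(locus.pseudo_start + s.pseudo_offset for s in locus.discordant_sites)
        assert diffs == expected
        assert len(diffs) == 4
        g0, g1 = locus.gene_interval
        assert all(not (g0 <= i < g1) for i in diffs)

    def test_empty_discordant_set_reproduces_buildA(self, locus):
        b = pc.render_reference(locus, "buildB", discordant_sites=())
        a = pc.render_reference(locus, "buildA")
        assert a.contig_seq == b.contig_seq

    def test_all_sites_discordant_collapses_core_divergence(self, locus):
        b = pc.render_reference(locus, "buildB", discordant_sites=locus.psv_sites)
        cs, cl = locus.params.core_start, locus.core_block_len
        g0 = locus.gene_start
        gene_core = b.contig_seq[g0 + cs:g0 + cs + cl]
        pseudo_core = b.contig_seq[locus.pseudo_start:locus.pseudo_start + cl]
        assert gene_core == pseudo_core

    def test_pure_given_inputs(self, locus):
        r1 = pc.render_reference(locus, "buildB")
        r2 = pc.render_reference(locus, "buildB")
        assert r1.contig_seq == r2.contig_seq and r1.registration == r2.registration

    def test_foreign_site_rejected(self, locus, mini_locus):
        with pytest.raises(ValueError):
            pc.render_reference(locus, "buildB",
                                discordant_sites=(mini_locus.psv_sites[0],))


class TestMakeSample:
    def test_case1_truth_is_het_pseudolike_snv(self, locus):
        s = pc.make_sample(locus, "case1_pseudolike_het_snv", 2)
        (t,) = s.truth
        site = locus.concordant_sites[0]
        assert t.zygosity == "het" and t.kind == "snv"
        assert t.alt == site.pseudo_major_allele
        assert t.ref_pos == locus.gene_pos(site.gene_offset)

    def test_case2_gene_truth_empty(self, locus):
        s = pc.make_sample(locus, "case2_control", 2)
        assert s.gene_truth() == []
        # the pseudogene haplotype carries the gene-like base that makes the
        # diagnostic read triple ambiguous
        (t,) = s.truth
        assert t.locus_copy == "pseudogene"

    def test_case4_truth_copy_numbers(self, locus):
        s = pc.make_sample(locus, "case4_gene_conversion_sv", 2)
        (t,) = s.truth
        assert (t.cn_gene, t.cn_pseudo) == (3, 1)
        d0, d1 = t.donor_interval
        c0, c1 = t.converted_interval
        e0, e1 = t.embedded_deletion
        assert d0 <= e0 < e1 <= d1 and e1 - e0 == 3
        # >=1 PSV within one fragment length upstream of the conversion start
        psv_pos = [locus.pseudo_pos(x.pseudo_offset) for x in locus.psv_sites]
        assert any(c0 - 450 <= p < c0 for p in psv_pos)

    def test_truth_recoverable_by_diff_against_buildA(self, locus):
        """Oracle: an independent global diff of haplotype 1 against the
        buildA contig recovers exactly the recorded small-variant truth."""
        ref = pc.render_reference(locus, "buildA").contig_seq
        for scen in ("case1_pseudolike_het_snv", "case2_control", "case3_gene_delins"):
            s = pc.make_sample(locus, scen, 2)
            diffs = _diff_single_gap(ref, s.haplotypes[1])
            from paraclone._variants import trim_and_left_align
            got = {trim_and_left_align(ref, *d) for d in diffs}
            want = {(t.ref_pos, t.ref, t.alt) for t in s.truth}
            assert got == want

    def test_case4_diff_recovers_replaced_interval_with_deletion(self, locus):
        s = pc.make_sample(locus, "case4_gene_conversion_sv", 2)
        ref = pc.render_reference(locus, "buildA").contig_seq
        hap = s.haplotypes[1]
        (t,) = s.truth
        c0, c1 = t.converted_interval
        d0, d1 = t.donor_interval
        e0, e1 = t.embedded_deletion
        assert hap[:c0] == ref[:c0]
        donor = ref[d0:e0] + ref[e1:d1]
        assert hap[c0:c0 + len(donor)] == donor
        assert hap[c0 + len(donor):] == ref[c1:]

    def test_haplotype0_is_reference_like(self, locus):
        for scen in pc.locus_forge.SCENARIOS:
            s = pc.make_sample(locus, scen, 2)
            assert len(s.haplotypes) == 2
            assert s.haplotypes[0] == locus.contig()

    def test_unknown_scenario_rejected(self, locus):
        with pytest.raises(ScenarioError):
            pc.make_sample(locus, "case9", 2)

    def test_delins_overlapping_psv_rejected(self, mini_params):
        import dataclasses
        bad = dataclasses.replace(mini_params, delins_interval=(455, 475))
        locus = pc.build_locus(5, bad)  # PSV at gene-local 450+... inside
        with pytest.raises(ScenarioError, match="PSV"):
            pc.make_sample(locus, "case3_gene_delins", 1)


class TestTruthSerialization:
    @pytest.mark.parametrize("scen,n_small", [
        ("case1_pseudolike_het_snv", 1),
        ("plain_control", 0),
        ("case3_gene_delins", 1),
    ])
    def test_truth_vcf_record_count(self, locus, tmp_path, scen, n_small):
        s = pc.make_sample(locus, scen, 2)
        vcf, bed = pc.write_truth(s, str(tmp_path))
        records = [l for l in open(vcf) if not l.startswith("#")]
        assert len(records) == n_small

    def test_roundtrip(self, locus, tmp_path):
        for scen in ("case1_pseudolike_het_snv", "case4_gene_conversion_sv"):
            s = pc.make_sample(locus, scen, 2)
            vcf, bed = pc.write_truth(s, str(tmp_path))
            back = pc.read_truth(vcf, bed)
            key = lambda t: (t.kind, t.locus_copy, t.ref_pos, t.ref, t.alt,
                             t.converted_interval, t.donor_interval,
                             t.embedded_deletion, t.cn_gene, t.cn_pseudo)
            assert sorted(map(key, back)) == sorted(map(key, s.truth))

    def test_case4_bed_reciprocal_gain_loss(self, locus, tmp_path):
        s = pc.make_sample(locus, "case4_gene_conversion_sv", 2)
        _, bed = pc.write_truth(s, str(tmp_path))
        rows = {l.split()[3]: l.split() for l in open(bed)}
        assert rows["gain_gene"][4] == "3"
        assert rows["loss_pseudo"][4] == "1"

    def test_reference_fasta_parses_with_standard_reader(self, locus, tmp_path):
        import pyfaidx
        ref = pc.render_reference(locus, "buildB")
        path = str(tmp_path / "buildB.fa")
        pc.reference_to_fasta(ref, path)
        fa = pyfaidx.Fasta(path)
        assert str(fa[locus.contig_name][:]) == ref.contig_seq
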