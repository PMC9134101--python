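"""Expression gate, I/L disambiguation, screens and the final label."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsakit.classify import (
    GateResult,
    NormalPanel,
    assign_source_transcript,
    expression_gate,
    final_label,
    il_disambiguate,
    il_variants,
    is_reference_peptide,
    localization_screen,
    normal_screen,
)
from tsakit.mcsquant import map_mcs


class TestExpressionGate:
    def test_tenfold_with_low_normal_passes(self):
        g = expression_gate(30.0, 1.5)
        assert g.passed and g.fold == pytest.approx(20.0)

    def test_high_normal_fails_despite_fold(self):
        assert not expression_gate(30.0, 2.5).passed

    def test_zero_normal_passes_with_infinite_fold(self):
        g = expression_gate(5.0, 0.0)
        assert g.passed and math.isinf(g.fold)

    def test_nothing_detected_fails(self):
        assert not expression_gate(0.0, 0.0).passed

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.floats(0, 100),
        st.floats(0, 10),
        st.floats(10, 30),
        st.floats(0.5, 3),
    )
    def test_monotone_in_thresholds(self, cancer, normal, fold2, max2):
        """Raising min_fold or lowering max_normal_kphm never turns a
        failing candidate into a passing one."""
        base = expression_gate(cancer, normal, 10.0, 2.0)
        stricter = expression_gate(cancer, normal, max(10.0, fold2), min(2.0, max2))
        if not base.passed:
            assert not stricter.passed


class TestIlDisambiguation:
    def test_no_il_residues_short_circuit(self):
        assert il_variants("MKTAYWAKW") == ["MKTAYWAKW"]

    def test_variant_enumeration(self):
        vs = il_variants("MIL")
        assert set(vs) == {"MIL", "MLL", "MII", "MLI"}

    def test_cap_falls_back_to_single_substitutions(self):
        pep = "ILILILILILI"  # 11 I/L residues
        with pytest.warns(UserWarning):
            vs = il_variants(pep, cap=10)
        assert len(vs) == 12

    def test_more_expressed_variant_drops_candidate(self):
        gate = GateResult(True, 50.0, 100.0, 2.0)
        kphm = {"SIIETVNSL": 10.0, "SLIETVNSL": 90.0}
        assert not il_disambiguate("SIIETVNSL", kphm, gate)

    def test_top_variant_kept_when_gate_passes(self):
        gate = GateResult(True, 50.0, 100.0, 2.0)
        kphm = {"SIIETVNSL": 90.0, "SLIETVNSL": 10.0}
        assert il_disambiguate("SIIETVNSL", kphm, gate)
        assert not il_disambiguate(
            "SIIETVNSL", kphm, GateResult(False, 1.0, 1.0, 1.0)
        )


class TestNormalScreen:
    def test_silent_panel_passes(self):
        assert normal_screen(NormalPanel({"liver": 0.0, "colon": 0.0})).passed

    def test_exact_threshold_fails_strictly(self):
        res = normal_screen(NormalPanel({"liver": 8.55}))
        assert not res.passed and res.failing_tissues == ["liver"]
        assert normal_screen(NormalPanel({"liver": 8.549})).passed

    def test_testis_exemption_flags_cancer_testis_antigen(self):
        panel = NormalPanel({"testis": 20.0, "liver": 0.0, "colon": 0.0})
        assert not normal_screen(panel).passed
        res = normal_screen(panel, exempt_mhc_low=True)
        assert res.passed and res.cta_flag

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            normal_screen(NormalPanel({}))


class TestLocalizationScreen:
    def test_region_labels_from_planted_events(self, planted):
        genome, truth = planted
        for ev in truth:
            if ev.kind == "mTSA_snv":
                continue
            hits = map_mcs(ev.expected_peptide, genome)
            res = localization_screen(hits, genome.annotation)
            assert res.passed
            assert res.region == ev.expected_region

    def test_no_hits_fail(self, planted):
        genome, _ = planted
        res = localization_screen([], genome.annotation)
        assert not res.passed and res.reason == "no_genomic_hit"

    def test_hypervariable_interval_fails(self, planted):
        genome, truth = planted
        ev = next(e for e in truth if e.kind == "aeTSA_intergenic")
        hits = map_mcs(ev.expected_peptide, genome)
        chrom, s, e_, _ = ev.locus
        res = localization_screen(
            hits, genome.annotation, hypervariable_loci=[(chrom, s - 100, e_ + 100)]
        )
        assert not res.passed and res.reason == "hypervariable_region"

    def test_too_many_loci_fail(self, planted):
        genome, truth = planted
        ev = next(e for e in truth if e.kind == "aeTSA_intergenic")
        hits = map_mcs(ev.expected_peptide, genome)
        fake = [
            type(h)(**{**vars(h), "start0": h.start0 + 100 * i, "end0": h.end0 + 100 * i})
            for h in hits
            for i in range(7)
        ]
        res = localization_screen(fake, genome.annotation, max_loci=5)
        assert not res.passed and res.reason == "ambiguous_localization"


class TestFinalLabel:
    GATE = GateResult(True, 20.0, 40.0, 2.0)

    def test_reference_matching_low_normals_is_aetsa(self):
        call = final_label(
            "PEP", "S1", self.GATE, is_mutated=False, is_germline=False,
            mtec_kphm=0.1, nat_kphm=0.05,
        )
        assert call.label == "aeTSA"

    def test_mtec_expression_makes_taa(self):
        call = final_label(
            "PEP", "S1", self.GATE, is_mutated=False, is_germline=False,
            mtec_kphm=0.5, nat_kphm=0.05,
        )
        assert call.label == "TAA"

    def test_somatic_variant_is_mtsa(self):
        call = final_label(
            "PEP", "S1", self.GATE, is_mutated=True, is_germline=False,
            mtec_kphm=0.0, nat_kphm=0.0,
        )
        assert call.label == "mTSA"

    def test_germline_variant_falls_through(self):
        call = final_label(
            "PEP", "S1", self.GATE, is_mutated=True, is_germline=True,
            mtec_kphm=0.0, nat_kphm=0.0,
        )
        assert call.label == "aeTSA"

    def test_cell_line_mode_ignores_nat(self):
        call = final_label(
            "PEP", "RKO", self.GATE, is_mutated=False, is_germline=False,
            mtec_kphm=0.1, nat_kphm=5.0, mode="cell_line",
        )
        assert call.label == "aeTSA"

    def test_failed_gate_is_excluded_with_reason(self):
        call = final_label(
            "PEP", "S1", GateResult(False, 1.0, 1.0, 1.0),
            is_mutated=False, is_germline=False, mtec_kphm=0.0,
        )
        assert call.label == "excluded"
        assert call.exclusion_reason == "expression_gate"

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.floats(0, 5), st.floats(0, 5), st.booleans(), st.booleans(),
        st.booleans(),
    )
    def test_exactly_one_label(self, mtec, nat, mut, germ, passed):
        gate = GateResult(passed, 15.0 if passed else 1.0, 10.0, 1.0)
        call = final_label(
            "PEP", "S1", gate, is_mutated=mut, is_germline=germ,
            mtec_kphm=mtec, nat_kphm=nat,
        )
        assert call.label in {"mTSA", "aeTSA", "TAA", "excluded"}
        assert (call.label == "excluded") == (call.exclusion_reason is not None)


class TestReferenceCheck:
    def test_mtsa_mcs_flagged_mutated(self, planted):
        genome, truth = planted
        ev = next(e for e in truth if e.kind == "mTSA_snv")
        tumor = type(genome)(dict(genome.chromosomes), genome.annotation,
                             genome.germline_snps)
        chrom, pos, ref, alt = ev.snv
        s = tumor.chromosomes[chrom]
        tumor.chromosomes[chrom] = s[:pos] + alt + s[pos + 1:]
        (hit,) = map_mcs(ev.expected_peptide, tumor)
        matches, germline = is_reference_peptide(hit, genome, genome.germline_snps)
        assert not matches and not germline
        # the same variant listed as a germline SNP is not somatic
        matches2, germline2 = is_reference_peptide(
            hit, genome, [(chrom, pos, ref, alt)]
        )
        assert not matches2 and germline2


class TestSourceTranscript:
    def test_highest_tpm_wins(self, planted):
        genome, truth = planted
        ev = next(e for e in truth if e.kind == "aeTSA_utr")
        (hit,) = map_mcs(ev.expected_peptide, genome)
        tpm = {tx.transcript_id: 5.0 for tx in genome.annotation}
        tpm[ev.host_transcript_id] = 50.0
        src = assign_source_transcript(hit, genome.annotation, tpm)
        assert src.transcript_id == ev.host_transcript_id
        assert not src.tie

    def test_no_overlap_is_unannotated(self, planted):
        genome, truth = planted
        ev = next(e for e in truth if e.kind == "aeTSA_intergenic")
        (hit,) = map_mcs(ev.expected_peptide, genome)
        src = assign_source_transcript(
            hit, genome.annotation, {}, region="intergenic"
        )
        assert src.transcript_id is None
        assert src.biotype == "intergenic"
        # default fallback without a region label
        assert (
            assign_source_transcript(hit, genome.annotation, {}).biotype
            == "unannotated"
        )

    def test_tie_is_deterministic_and_flagged(self, planted):
        import dataclasses

        genome, _ = planted
        tx = next(t for t in genome.annotation if t.cds is not None)
        twin = dataclasses.replace(tx, transcript_id="TXZZZ")
        annotation = list(genome.annotation) + [twin]
        hit = type(
            "H", (),
            dict(chrom=tx.chrom, start0=tx.start + 1, end0=tx.start + 28,
                 strand=tx.strand),
        )
        tpm = {t.transcript_id: 10.0 for t in annotation}
        src = assign_source_transcript(hit, annotation, tpm)
        assert src.tie
        assert src.transcript_id == tx.transcript_id  # lexicographic minimum
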