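"""Reverse translation, exact MCS placement, RPHM/KPHM quantification."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from tsakit.kmerdb import KmerSet, count_kmers
from tsakit.mcsquant import (
    kphm_quantify,
    map_mcs,
    mcs_pattern,
    reverse_translate,
    rphm_quantify,
)
from tsakit.seqs import BACK_TABLE
from tsakit.syndata import (
    ReadSet,
    ToyGenome,
    TranscriptModel,
    genomic_positions,
    make_toy_genome,
    simulate_reads,
)


class TestReverseTranslate:
    def test_single_codon_residues(self):
        rt = reverse_translate("MW")
        assert rt.n_sequences == 1
        assert rt.sequences == ["ATGTGG"]

    def test_lysine_degeneracy(self):
        rt = reverse_translate("KK")
        assert rt.n_sequences == 4

    def test_explicit_enumeration(self):
        rt = reverse_translate("MKW")
        assert rt.n_sequences == 2
        assert set(rt.sequences) == {"ATGAAATGG", "ATGAAGTGG"}

    def test_count_matches_brute_force_product(self):
        rng = np.random.default_rng(23)
        aas = list(BACK_TABLE)
        for _ in range(50):
            pep = "".join(rng.choice(aas, 4))
            rt = reverse_translate(pep, max_enumeration=10**6)
            brute = [
                "".join(c)
                for c in itertools.product(*(BACK_TABLE[a] for a in pep))
            ]
            assert rt.n_sequences == len(brute) == len(set(brute))
            assert set(rt.sequences) == set(brute)
            # every enumerated sequence translates back to the peptide
            assert all(str(Seq(s).translate()) == pep for s in brute[:5])

    def test_enumeration_suppressed_above_cap(self):
        rt = reverse_translate("LLLLLLLL", max_enumeration=10)
        assert rt.n_sequences == 6**8
        assert rt.sequences is None

    def test_unknown_residue(self):
        with pytest.raises(ValueError):
            reverse_translate("MKX")


class TestMapMcs:
    def test_planted_event_found_at_locus(self, planted):
        genome, truth = planted
        for ev in truth:
            if ev.kind == "mTSA_snv":
                continue  # mutant allele is not in the reference genome
            hits = map_mcs(ev.expected_peptide, genome)
            assert len(hits) == 1
            h = hits[0]
            assert (h.chrom, h.start0, h.end0, h.strand) == ev.locus
            assert h.mcs == ev.mcs

    def test_absent_peptide_has_no_hits(self, toy_genome):
        # tryptophan-rich nonamer: single MCS, absent from a random genome
        assert map_mcs("WWWWWWWWW", toy_genome) == []

    def test_junction_spanning_hit(self):
        rng = np.random.default_rng(31)
        chrom = "".join(rng.choice(list("ACGT"), 800))
        tx = TranscriptModel(
            "TXJ", "GJ", "protein_coding", "chrJ", "+",
            exons=[(50, 130), (330, 410)], cds=(5, 155),
        )
        genome = ToyGenome({"chrJ": chrom}, [tx])
        pep = "MKTAYIAKW"
        mcs = "".join(BACK_TABLE[a][0] for a in pep)
        # write codons across the exon-exon junction (spliced pos 66..93)
        pos_map = genomic_positions(tx)
        chars = list(chrom)
        for i, base in enumerate(mcs):
            chars[pos_map[66 + i]] = base
        genome.chromosomes["chrJ"] = "".join(chars)
        hits = map_mcs(pep, genome)
        spliced_hits = [h for h in hits if h.spliced]
        assert len(spliced_hits) == 1
        h = spliced_hits[0]
        assert h.transcript_id == "TXJ"
        assert len(h.segments) == 2
        ref = "".join(genome.chromosomes["chrJ"][a:b] for a, b in h.segments)
        assert ref == mcs

    def test_minus_strand_hit_retranslates(self):
        rng = np.random.default_rng(37)
        pep = "MKTAYIAKW"
        mcs = "".join(BACK_TABLE[a][0] for a in pep)
        chrom = (
            "".join(rng.choice(list("ACGT"), 100))
            + str(Seq(mcs).reverse_complement())
            + "".join(rng.choice(list("ACGT"), 100))
        )
        genome = ToyGenome({"chrM": chrom}, [])
        hits = map_mcs(pep, genome)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert str(Seq(hits[0].mcs).translate()) == pep

    def test_pattern_matches_only_true_coding_sequences(self):
        # positional IUPAC for L would admit TTT (Phe); the codon
        # alternation pattern must not
        pat = mcs_pattern("L")
        assert pat.search("TTA") and pat.search("CTG")
        assert not pat.search("TTT")


class TestQuantification:
    def test_rphm_formula_and_zero(self):
        mcs = "ATGAAAACCGCTTACATCGCTAAATGG"
        hit = type("H", (), {"mcs": mcs})  # minimal stand-in carrying .mcs
        pad = "ACGT" * 12
        reads = [pad[: 48 - len(mcs)] + mcs for _ in range(10)]
        reads += ["A" * 48 for _ in range(40)]
        rs = ReadSet("s", reads, 50, read_len=48)
        count, rphm = rphm_quantify("X", [hit], rs)
        assert count == 10
        assert rphm == 10 * 1e8 / 50
        count0, rphm0 = rphm_quantify("X", [hit], ReadSet("s", ["A" * 48], 1, read_len=48))
        assert (count0, rphm0) == (0, 0.0)
        with pytest.raises(ValueError):
            rphm_quantify("X", [hit], ReadSet("s", [], 0))

    def test_rphm_monotone_in_depth(self, toy_genome):
        # the library total is dominated by a fixed background so rtot is
        # near-constant while the feature depth doubles
        chroms = list(toy_genome.chromosomes)
        window = (chroms[0], 1000, 2000, "+")
        background = (chroms[1], 0, 30_000, "+")
        mcs = toy_genome.chromosomes[chroms[0]][1480:1507]
        hit = type("H", (), {"mcs": mcs})
        values = []
        for depth in (5, 10, 20):
            rs = simulate_reads(
                toy_genome, {window: float(depth), background: 20.0}, seed=41
            )
            _, rphm = rphm_quantify("X", [hit], rs)
            values.append(rphm)
        assert values[0] < values[1] < values[2]
        # doubling depth roughly doubles rphm (Poisson tolerance)
        assert values[2] / values[1] == pytest.approx(2.0, rel=0.45)

    def test_kphm_minimum_and_formula(self):
        mcs = "A" * 30
        counts = {}
        for i in range(len(mcs) - 23):
            counts[mcs[i : i + 24]] = 7  # all identical windows for A-run
        db = KmerSet(24, {"A" * 24: 7}, rtot=10**8, canonical=True)
        kmin, kphm = kphm_quantify("X", [mcs], db)
        assert kmin == 7
        db2 = KmerSet(24, {"A" * 24: 5}, rtot=2 * 10**8, canonical=True)
        kmin2, kphm2 = kphm_quantify("X", [mcs], db2)
        assert (kmin2, kphm2) == (5, 2.5)

    def test_kphm_zero_when_any_window_absent(self, planted):
        genome, truth = planted
        ev = next(e for e in truth if e.kind == "aeTSA_intergenic")
        normal_prof = {
            tx.transcript_id: 20.0 for tx in genome.annotation if tx.cds is not None
        }
        normal = simulate_reads(genome, normal_prof, seed=43, sample_id="n")
        db = count_kmers(normal, 24, canonical=True)
        kmin, kphm = kphm_quantify(ev.expected_peptide, [ev.mcs], db)
        assert (kmin, kphm) == (0, 0.0)

    def test_kphm_requires_canonical_24mers(self):
        with pytest.raises(ValueError):
            kphm_quantify("X", ["A" * 30], KmerSet(24, {}, 1, canonical=False))
        with pytest.raises(ValueError):
            kphm_quantify("X", ["A" * 20], KmerSet(24, {}, 1, canonical=True))

    def test_duplication_invariance(self):
        """Duplicating the whole library while doubling rtot is a no-op."""
        rng = np.random.default_rng(47)
        mcs = "".join(rng.choice(list("ACGT"), 27))
        reads = [mcs + "".join(rng.choice(list("ACGT"), 21)) for _ in range(5)]
        reads += ["".join(rng.choice(list("ACGT"), 48)) for _ in range(5)]
        rs1 = ReadSet("s", reads, len(reads), read_len=48)
        rs2 = ReadSet("s", reads * 2, 2 * len(reads), read_len=48)
        hit = type("H", (), {"mcs": mcs})
        assert rphm_quantify("X", [hit], rs1)[1] == rphm_quantify("X", [hit], rs2)[1]
        db1 = count_kmers(rs1, 24, canonical=True)
        db2 = count_kmers(rs2, 24, canonical=True)
        assert (
            kphm_quantify("X", [mcs], db1)[1] == kphm_quantify("X", [mcs], db2)[1]
        )
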