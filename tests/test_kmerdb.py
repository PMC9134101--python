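"""K-mer counting, normal subtraction, unitig assembly, database build."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsakit.kmerdb import (
    KmerSet,
    assemble_contigs,
    build_global_db,
    count_kmers,
    read_kmerset,
    split_db_entry,
    subtract_normal,
    translate_3frame,
    write_kmerset,
)
from tsakit.seqs import revcomp


def naive_counts(reads, k, canonical):
    out = Counter()
    for r in reads:
        for i in range(len(r) - k + 1):
            km = r[i : i + k]
            if set(km) - set("ACGT"):
                continue
            out[min(km, revcomp(km)) if canonical else km] += 1
    return dict(out)


def random_reads(rng, n, length=75):
    return ["".join(rng.choice(list("ACGT"), length)) for _ in range(n)]


class TestCountKmers:
    def test_sliding_window(self):
        ks = count_kmers(["ACGTACGTA"], k=8)
        assert ks.counts == {"ACGTACGT": 1, "CGTACGTA": 1}
        assert ks.rtot == 1

    def test_canonical_merges_reverse_complement(self):
        ks = count_kmers(["AAAA", "TTTT"], k=4, canonical=True)
        assert ks.counts == {"AAAA": 2}

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(42)
        reads = random_reads(rng, 100)
        for canonical in (False, True):
            ks = count_kmers(reads, k=24, canonical=canonical)
            assert ks.counts == naive_counts(reads, 24, canonical)

    def test_skips_ambiguous_bases_and_validates_k(self):
        ks = count_kmers(["ACGNACGT"], k=4)
        assert all("N" not in km for km in ks.counts)
        with pytest.raises(ValueError):
            count_kmers(["ACGT"], k=10)


class TestSubtractNormal:
    def test_paper_threshold_semantics(self):
        tumor = KmerSet(4, {"AAAA": 5, "CCCC": 3, "GGGG": 2}, rtot=10)
        normal = KmerSet(4, {"CCCC": 2, "GGGG": 1}, rtot=10)
        kept = subtract_normal(tumor, [normal], max_count=2)
        # absent -> kept; normal count 2 -> removed; count 1 -> kept
        assert kept.counts == {"AAAA": 5, "GGGG": 2}

    def test_counts_pool_across_normals(self):
        tumor = KmerSet(4, {"AAAA": 5}, rtot=10)
        n1 = KmerSet(4, {"AAAA": 1}, rtot=10)
        kept = subtract_normal(tumor, [n1, n1], max_count=2)
        assert kept.counts == {}

    def test_mismatched_k_rejected(self):
        with pytest.raises(ValueError):
            subtract_normal(
                KmerSet(4, {}, 1), [KmerSet(5, {}, 1)]
            )

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            tumor = count_kmers(random_reads(rng, 10, 40), k=8)
            normals = [count_kmers(random_reads(rng, 10, 40), k=8) for _ in range(2)]
            kept = subtract_normal(tumor, normals, max_count=2)
            expected = {
                km: c
                for km, c in tumor.counts.items()
                if sum(n.counts.get(km, 0) for n in normals) < 2
            }
            assert kept.counts == expected


class TestAssembleContigs:
    def test_reconstructs_source_string(self):
        rng = np.random.default_rng(3)
        # a string with all-distinct 8-mers assembles back to itself
        while True:
            s = "".join(rng.choice(list("ACGT"), 40))
            kmers = [s[i : i + 8] for i in range(len(s) - 7)]
            if len(set(kmers)) == len(kmers):
                break
        ks = count_kmers([s], k=8)
        contigs = assemble_contigs(ks)
        assert [c.sequence for c in contigs] == sorted([s])

    def test_isolated_kmer(self):
        ks = KmerSet(8, {"ACGTACGT": 1}, rtot=1)
        (c,) = assemble_contigs(ks)
        assert c.sequence == "ACGTACGT" and c.n_kmers == 1

    def test_fork_stops_extension(self):
        # AAACCC -> {AACCCA, AACCCG} : shared (k-1)-prefix forks the graph
        ks = KmerSet(6, {"AAACCC": 1, "AACCCA": 1, "AACCCG": 1}, rtot=1)
        contigs = assemble_contigs(ks)
        seqs = {c.sequence for c in contigs}
        # no contig may contain a k-mer absent from the input
        for c in contigs:
            for i in range(len(c.sequence) - 5):
                assert c.sequence[i : i + 6] in ks.counts
        assert sum(c.n_kmers for c in contigs) == 3
        assert any(s.startswith("AAACCC") for s in seqs)

    def test_conservation_invariant(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            ks = count_kmers(random_reads(rng, 20, 50), k=12)
            contigs = assemble_contigs(ks)
            seen = Counter()
            for c in contigs:
                for i in range(len(c.sequence) - 11):
                    seen[c.sequence[i : i + 12]] += 1
            assert set(seen) == set(ks.counts)
            assert all(v == 1 for v in seen.values())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assemble_contigs(KmerSet(8, {}, 0))


class TestTranslate3Frame:
    def test_short_fragments_dropped_by_default(self):
        assert translate_3frame("ATGAAATAG") == []

    def test_min_length_one(self):
        # frame 0 gives "M" before the stop; frames 1/2 contribute their
        # single-residue translations as well
        assert translate_3frame("ATGTGA", min_len=1) == ["M", "C", "V"]

    def test_planted_peptide_recovered(self):
        # frame-1 planted nonamer inside a contig
        from tsakit.seqs import BACK_TABLE

        pep = "MKTAYIAKW"
        mcs = "".join(BACK_TABLE[a][0] for a in pep)
        contig = "G" + mcs + "CC"
        frags = translate_3frame(contig, min_len=8)
        assert any(pep in f for f in frags)

    def test_six_frame_option(self):
        from tsakit.seqs import BACK_TABLE

        pep = "MKTAYIAKW"
        mcs = "".join(BACK_TABLE[a][0] for a in pep)
        contig = revcomp("G" + mcs + "CC")
        assert not any(pep in f for f in translate_3frame(contig))
        assert any(pep in f for f in translate_3frame(contig, both_strands=True))


class TestBuildGlobalDb:
    def test_jj_separator(self):
        db = build_global_db([], ["MKL", "QRS"], target_len=10)
        assert db.entries == [("csdb|0001", "MKLJJQRS")]
        assert db.origins == ["cancer_specific"]

    def test_empty_fragments_keep_canonical_only(self):
        db = build_global_db([("p1", "MKTAY")], [], target_len=10)
        assert db.entries == [("p1", "MKTAY")]
        assert db.origins == ["canonical"]

    def test_round_trip_recovers_fragment_multiset(self):
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        frags = ["".join(rng.choice(aas, 9)) for _ in range(1000)]
        db = build_global_db([], frags, target_len=100)
        back = []
        for (_, seq), origin in zip(db.entries, db.origins):
            assert origin == "cancer_specific"
            assert len(seq) <= 100
            back.extend(split_db_entry(seq))
        assert Counter(back) == Counter(frags)

    def test_j_fragment_rejected(self):
        with pytest.raises(ValueError):
            build_global_db([], ["MKJ"], target_len=10)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(
        st.text(alphabet="ACGT", min_size=12, max_size=40), min_size=1, max_size=8
    )
)
def test_subtraction_soundness_property(reads):
    """No surviving k-mer has pooled normal occurrence >= the threshold."""
    tumor = count_kmers(reads, k=8)
    normal = count_kmers(reads[::2], k=8)
    if not tumor.counts:
        return
    kept = subtract_normal(tumor, [normal], max_count=2)
    for km in kept.counts:
        assert normal.counts.get(km, 0) < 2


def test_kmerset_tsv_round_trip(tmp_path):
    ks = count_kmers(["ACGTACGTAAAT", "TTTACCGGTAAA"], k=6, canonical=True)
    path = tmp_path / "kmers.tsv"
    write_kmerset(path, ks)
    back = read_kmerset(path)
    assert back.k == ks.k and back.canonical == ks.canonical
    assert back.rtot == ks.rtot and back.counts == ks.counts
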