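"""Reverse translation, exact genomic placement and expression of MAP
coding sequences (MCSs).

A peptide's MCSs are all nucleotide sequences able to encode it.  They are
located by exact matching against both genome strands and against spliced
transcript sequences (to catch junction-spanning peptides), and expression
is quantified two ways:

* RPHM — reads fully containing an MCS, per 10^8 sequenced reads;
* KPHM — ``kmin * 1e8 / rtot`` where kmin is the minimum occurrence of the
  MCS's 24-nt k-mers in a canonical (reverse-complement-merged) k-mer
  database; one k-mer generally originates from a single read, so kmin
  estimates the number of reads fully overlapping the coding sequence.

Enumerating all MCSs is exponential in sequence degeneracy, so matching
uses a per-residue codon-alternation regular expression (exact by
construction) and only enumerates explicitly below ``max_enumeration``.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .kmerdb import KmerSet
from .seqs import BACK_TABLE, iupac_codon, revcomp, translate
from .syndata import ReadSet, ToyGenome, TranscriptModel, genomic_positions


@dataclass
class ReverseTranslation:
    peptide: str
    degenerate: str  # positional IUPAC summary (display form)
    n_sequences: int  # exact count: product of codon degeneracies
    sequences: list[str] | None  # explicit enumeration when feasible


@dataclass
class McsHit:
    peptide: str
    mcs: str  # sense-strand coding sequence found at the locus
    chrom: str
    start0: int
    end0: int
    strand: str
    spliced: bool = False
    transcript_id: str | None = None
    segments: list[tuple[int, int]] | None = None  # genomic pieces of spliced hits


@dataclass
class ExpressionProfile:
    peptide: str
    samples: dict[str, dict] = field(default_factory=dict)

    def set(self, sample: str, kmin: int = 0, kphm: float = 0.0,
            read_count: int = 0, rphm: float = 0.0) -> None:
        self.samples[sample] = dict(
            kmin=kmin, kphm=kphm, read_count=read_count, rphm=rphm
        )

    def kphm(self, sample: str) -> float:
        return self.samples[sample]["kphm"]

    def rphm(self, sample: str) -> float:
        return self.samples[sample]["rphm"]


def reverse_translate(peptide: str, max_enumeration: int = 100_000) -> ReverseTranslation:
    """All nucleotide sequences able to code for ``peptide``.

    Returns the positional IUPAC summary, the exact count of distinct
    coding sequences, and the explicit enumeration when the count does not
    exceed ``max_enumeration``.
    """
    unknown = set(peptide) - set(BACK_TABLE)
    if unknown:
        raise ValueError(f"unknown residue(s): {sorted(unknown)}")
    n = 1
    for aa in peptide:
        n *= len(BACK_TABLE[aa])
    sequences = None
    if n <= max_enumeration:
        sequences = [
            "".join(codons)
            for codons in itertools.product(*(BACK_TABLE[aa] for aa in peptide))
        ]
    return ReverseTranslation(
        peptide=peptide,
        degenerate="".join(iupac_codon(aa) for aa in peptide),
        n_sequences=n,
        sequences=sequences,
    )


def mcs_pattern(peptide: str) -> re.Pattern:
    """Exact codon-alternation regex matching every MCS of the peptide.

    Wrapped in a lookahead capture so overlapping occurrences are found.
    """
    body = "".join("(?:%s)" % "|".join(BACK_TABLE[aa]) for aa in peptide)
    return re.compile(f"(?=({body}))")


def map_mcs(
    peptide: str,
    genome: ToyGenome,
    transcripts: Sequence[TranscriptModel] | None = None,
) -> list[McsHit]:
    """Exact placement of every MCS on the genome and spliced transcriptome.

    Both genome strands are searched; spliced transcript sequences catch
    junction-spanning coding sequences, which are projected back onto
    genomic segments.  Results are deduplicated and sorted by
    (chrom, start0).  An empty list flags unclear localization downstream.
    """
    pat = mcs_pattern(peptide)
    width = 3 * len(peptide)
    hits: dict[tuple, McsHit] = {}

    for chrom, seq in genome.chromosomes.items():
        for m in pat.finditer(seq):
            s = m.start()
            hits[(chrom, s, s + width, "+")] = McsHit(
                peptide, m.group(1), chrom, s, s + width, "+"
            )
        rc = revcomp(seq)
        L = len(seq)
        for m in pat.finditer(rc):
            s = m.start()
            g0, g1 = L - (s + width), L - s
            hits[(chrom, g0, g1, "-")] = McsHit(
                peptide, m.group(1), chrom, g0, g1, "-"
            )

    for tx in transcripts if transcripts is not None else genome.annotation:
        spliced = genome.spliced(tx)
        pos_map = genomic_positions(tx)
        for m in pat.finditer(spliced):
            s = m.start()
            gpos = pos_map[s : s + width]
            segments: list[tuple[int, int]] = []
            step = -1 if tx.strand == "-" else 1
            seg_start = gpos[0]
            prev = gpos[0]
            for g in gpos[1:]:
                if g - prev != step:
                    segments.append(tuple(sorted((seg_start, prev))))
                    seg_start = g
                prev = g
            segments.append(tuple(sorted((seg_start, prev))))
            if len(segments) == 1:
                continue  # contiguous: already found genomically
            segments = [(a, b + 1) for a, b in sorted(segments)]
            key = (tx.chrom, segments[0][0], segments[-1][1], tx.strand, tx.transcript_id)
            hits[key] = McsHit(
                peptide,
                m.group(1),
                tx.chrom,
                segments[0][0],
                segments[-1][1],
                tx.strand,
                spliced=True,
                transcript_id=tx.transcript_id,
                segments=segments,
            )

    out = sorted(hits.values(), key=lambda h: (h.chrom, h.start0, h.end0, h.strand))
    for h in out:
        assert translate(h.mcs) == peptide
    return out


def rphm_quantify(
    peptide: str, hits: Sequence[McsHit], readset: ReadSet
) -> tuple[int, float]:
    """Reads fully containing any located MCS, normalized per 10^8 reads.

    A read counts when the complete coding sequence is a substring of it
    (sense orientation; the reverse complement is also checked for
    unstranded libraries).
    """
    if readset.total_reads == 0:
        raise ValueError("rphm undefined for an empty read set")
    needles = {h.mcs for h in hits}
    if not readset.stranded:
        needles |= {revcomp(m) for m in needles}
    count = sum(1 for r in readset.reads if any(m in r for m in needles))
    return count, count * 1e8 / readset.total_reads


def kphm_quantify(
    peptide: str,
    mcs_set: Iterable[str],
    kmer24: KmerSet,
    mode: str = "max",
) -> tuple[int, float]:
    """Minimum 24-mer occurrence of the most-expressed MCS, per 10^8 reads.

    For each candidate coding sequence, kmin is the minimum occurrence of
    its 24-nt sliding windows in the canonical k-mer database (an absent
    k-mer gives 0).  ``mode='max'`` takes the MCS whose kmin is maximal
    (the most-expressed variant); ``mode='single'`` requires exactly one
    MCS.  kphm follows the exact formula kmin * 1e8 / rtot.
    """
    if kmer24.k != 24 or not kmer24.canonical:
        raise ValueError("kphm requires a canonical 24-mer database")
    mcs_list = list(mcs_set)
    if mode == "single" and len(mcs_list) != 1:
        raise ValueError("mode='single' requires exactly one MCS")
    kmin = 0
    for mcs in mcs_list:
        if len(mcs) < 24:
            raise ValueError("MCS shorter than 24 nt")
        this = min(
            kmer24.get(mcs[i : i + 24]) for i in range(len(mcs) - 23)
        )
        kmin = max(kmin, this)
    return kmin, kmin * 1e8 / kmer24.rtot


def profile_peptide(
    peptide: str,
    hits: Sequence[McsHit],
    kmer_dbs: Mapping[str, KmerSet],
    readsets: Mapping[str, ReadSet] | None = None,
) -> ExpressionProfile:
    """KPHM across k-mer databases plus RPHM across read sets."""
    prof = ExpressionProfile(peptide)
    mcs_set = {h.mcs for h in hits}
    for sample, db in kmer_dbs.items():
        if mcs_set:
            kmin, kphm = kphm_quantify(peptide, mcs_set, db)
        else:
            kmin, kphm = 0, 0.0
        prof.set(sample, kmin=kmin, kphm=kphm)
    for sample, rs in (readsets or {}).items():
        count, rphm = rphm_quantify(peptide, hits, rs) if mcs_set else (0, 0.0)
        entry = prof.samples.setdefault(
            sample, dict(kmin=0, kphm=0.0, read_count=0, rphm=0.0)
        )
        entry["read_count"] = count
        entry["rphm"] = rphm
    return prof


def hits_to_bed(hits: Sequence[McsHit]) -> str:
    """BED-like TSV: chrom, start0, end0, name=peptide, score=., strand."""
    lines = [
        f"{h.chrom}\t{h.start0}\t{h.end0}\t{h.peptide}\t.\t{h.strand}"
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")
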