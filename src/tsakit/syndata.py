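"""Self-contained toy tumor/normal study generator.

Everything downstream of the wet lab is emulated here: a small reference
genome with spliced protein-coding and lncRNA transcript models, planted
antigen-generating events (tumor-restricted transcription of intronic,
intergenic, UTR and lncRNA windows; a somatic SNV; alternative-frame exon
peptides; overexpressed canonical genes), stranded error-free fixed-length
read sets, and search-engine-like identification and TMT quantitation
tables with decoys and binding ranks.  The planted truth is recorded so
that the classification cascade can be tested by parameter recovery.

Reads are single-end, error-free, 75 nt and emitted in transcript (sense)
orientation, emulating a stranded library; an option flips a configurable
fraction to antisense.  Coordinates are 0-based half-open, strands '+'/'-'.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .mapfilter import MapRecord
from .quantms import PsmQuantRecord, SpectrumPair
from .seqs import (
    AMINO_ACIDS,
    BACK_TABLE,
    SENSE_CODONS,
    complement,
    revcomp,
    translate,
)

BIOTYPES = (
    "protein_coding",
    "lncRNA",
    "processed_transcript",
    "retained_intron",
    "nonsense_mediated_decay",
    "nonstop_decay",
)

EVENT_KINDS = (
    "aeTSA_intron",
    "aeTSA_intergenic",
    "aeTSA_lncRNA",
    "aeTSA_utr",
    "aeTSA_frameshift",
    "mTSA_snv",
    "TAA_overexpressed",
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# domain types


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    biotype: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genomic, 0-based half-open, sorted by start
    cds: tuple[int, int] | None = None  # in spliced (stranded) coordinates

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if self.cds is not None and (self.cds[1] - self.cds[0]) % 3:
            raise ValueError("CDS length must be divisible by 3")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(b - a for a, b in self.exons)


@dataclass
class ToyGenome:
    chromosomes: dict[str, str]
    annotation: list[TranscriptModel]
    germline_snps: list[tuple[str, int, str, str]] = field(default_factory=list)

    def spliced(self, tx: TranscriptModel) -> str:
        s = "".join(self.chromosomes[tx.chrom][a:b] for a, b in tx.exons)
        return revcomp(s) if tx.strand == "-" else s

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for tx in self.annotation:
            if tx.transcript_id == transcript_id:
                return tx
        raise KeyError(transcript_id)

    def validate(self) -> None:
        for name, seq in self.chromosomes.items():
            if set(seq) - set("ACGT"):
                raise ValueError(f"{name}: non-ACGT characters")
        for tx in self.annotation:
            clen = len(self.chromosomes[tx.chrom])
            prev_end = -1
            for a, b in tx.exons:
                if not (0 <= a < b <= clen):
                    raise ValueError(f"{tx.transcript_id}: exon out of bounds")
                if a <= prev_end:
                    raise ValueError(f"{tx.transcript_id}: exons overlap/unsorted")
                prev_end = b
            if tx.cds is not None:
                cs, ce = tx.cds
                if not (0 <= cs < ce <= tx.spliced_length):
                    raise ValueError(f"{tx.transcript_id}: CDS outside transcript")


def genomic_positions(tx: TranscriptModel) -> list[int]:
    """Genomic position of every spliced base, in transcript (5'->3') order."""
    pos = [g for a, b in tx.exons for g in range(a, b)]
    return pos[::-1] if tx.strand == "-" else pos


@dataclass
class PlantedEvent:
    kind: str
    locus: tuple[str, int, int, str]  # genomic span of the coding sequence
    expected_peptide: str
    mcs: str  # the sense-strand coding nucleotide sequence
    tumor_depth: float
    normal_depth: float
    mtec_depth: float
    feature: tuple[str, int, int, str] | None = None  # expressed window
    host_transcript_id: str | None = None
    snv: tuple[str, int, str, str] | None = None  # genomic (chrom,pos0,ref,alt)
    expected_region: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind.startswith("aeTSA") and (self.normal_depth or self.mtec_depth):
            raise ValueError("aeTSA events must have zero normal/mTEC depth")
        if self.kind == "TAA_overexpressed" and self.tumor_depth < 10 * self.normal_depth:
            raise ValueError("TAA events require tumor_depth >= 10x normal_depth")

    @property
    def expected_label(self) -> str:
        if self.kind == "mTSA_snv":
            return "mTSA"
        if self.kind == "TAA_overexpressed":
            return "TAA"
        return "aeTSA"


@dataclass
class EventRequest:
    kind: str
    peptide_length: int = 9
    tumor_depth: float = 20.0
    normal_depth: float = 0.0
    mtec_depth: float = 0.0


@dataclass
class ReadSet:
    sample_id: str
    reads: list[str]
    total_reads: int
    stranded: bool = True
    read_len: int = 75

    def __post_init__(self) -> None:
        if self.total_reads != len(self.reads):
            raise ValueError("total_reads must equal number of reads")


# ---------------------------------------------------------------------------
# genome construction


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(len(SENSE_CODONS), n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in codons)


def make_toy_genome(
    seed: int,
    n_chrom: int = 2,
    chrom_len: int = 50_000,
    n_genes: int = 6,
    n_lncrna: int = 2,
    n_germline_snps: int = 5,
) -> ToyGenome:
    """Random genome with multi-exon protein-coding genes and lncRNAs.

    Genes have UTR5/CDS/UTR3 structure over >=2 exons, CDSs translate
    without internal stop codons, intergenic gaps are >=500 nt, and the
    result is deterministic for a fixed seed.
    """
    if chrom_len < 10_000:
        raise ValueError("chrom_len must be >= 10,000")
    if n_genes < 4:
        raise ValueError("n_genes must be >= 4")
    rng = np.random.default_rng(seed)
    chroms = {f"chr{i + 1}": list(_random_seq(rng, chrom_len)) for i in range(n_chrom)}
    names = list(chroms)
    cursors = {c: 600 for c in names}
    annotation: list[TranscriptModel] = []

    specs = [("protein_coding", i) for i in range(n_genes)]
    specs += [("lncRNA", n_genes + i) for i in range(n_lncrna)]
    for biotype, idx in specs:
        chrom = names[idx % n_chrom]
        start = cursors[chrom] + 500 + int(rng.integers(0, 300))
        strand = "+" if rng.random() < 0.5 else "-"
        if biotype == "protein_coding":
            utr5 = int(rng.integers(80, 160))
            n_codons = int(rng.integers(100, 181))
            utr3 = int(rng.integers(120, 220))
            mrna = (
                _random_seq(rng, utr5)
                + _random_cds(rng, n_codons)
                + _random_seq(rng, utr3)
            )
            cds = (utr5, utr5 + 3 * n_codons)
            n_exons = int(rng.integers(2, 5))
        else:
            mrna = _random_seq(rng, int(rng.integers(320, 480)))
            cds = None
            n_exons = 2
        base = len(mrna) // n_exons
        exon_lens = [base] * (n_exons - 1) + [len(mrna) - base * (n_exons - 1)]
        intron_lens = [int(x) for x in rng.integers(150, 401, n_exons - 1)]
        exons = []
        g = start
        for i, el in enumerate(exon_lens):
            exons.append((g, g + el))
            g += el + (intron_lens[i] if i < len(intron_lens) else 0)
        end = exons[-1][1]
        if end + 600 > chrom_len:
            raise ValueError(
                f"chrom_len={chrom_len} too small to place {n_genes} genes"
            )
        placed = mrna if strand == "+" else revcomp(mrna)
        off = 0
        for a, b in exons:
            chroms[chrom][a:b] = placed[off : off + (b - a)]
            off += b - a
        annotation.append(
            TranscriptModel(
                transcript_id=f"TX{idx:03d}",
                gene_id=f"G{idx:03d}",
                biotype=biotype,
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds=cds,
            )
        )
        cursors[chrom] = end

    genome = ToyGenome({c: "".join(s) for c, s in chroms.items()}, annotation)
    spans = [(tx.chrom, tx.start, tx.end) for tx in annotation]
    snps: list[tuple[str, int, str, str]] = []
    attempts = 0
    while len(snps) < n_germline_snps and attempts < 1000:
        attempts += 1
        chrom = names[int(rng.integers(0, n_chrom))]
        pos = int(rng.integers(100, chrom_len - 100))
        if any(c == chrom and s - 50 <= pos < e + 50 for c, s, e in spans):
            continue
        ref = genome.chromosomes[chrom][pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        snps.append((chrom, pos, ref, alt))
    genome.germline_snps = snps
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# event planting


def canonical_proteins(genome: ToyGenome) -> dict[str, str]:
    """gene_id -> CDS translation for every protein-coding transcript."""
    out = {}
    for tx in genome.annotation:
        if tx.cds is None:
            continue
        cs, ce = tx.cds
        out[tx.gene_id] = translate(genome.spliced(tx)[cs:ce])
    return out


def _occurs_once(chroms: Mapping[str, str], mcs: str) -> bool:
    fwd = sum(seq.count(mcs) for seq in chroms.values())
    rev = sum(seq.count(revcomp(mcs)) for seq in chroms.values())
    return fwd + rev == 1


def _absent(chroms: Mapping[str, str], mcs: str) -> bool:
    return not any(mcs in seq or revcomp(mcs) in seq for seq in chroms.values())


def _random_peptide(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, n))


def _encode(rng: np.random.Generator, peptide: str) -> str:
    return "".join(
        BACK_TABLE[aa][int(rng.integers(0, len(BACK_TABLE[aa])))] for aa in peptide
    )


def _exonic_window(tx: TranscriptModel, pos_map: list[int], s: int, e: int) -> bool:
    """True if spliced interval [s, e) is contiguous on the genome."""
    if e > len(pos_map):
        return False
    step = -1 if tx.strand == "-" else 1
    piece = pos_map[s:e]
    return all(piece[i + 1] - piece[i] == step for i in range(len(piece) - 1))


class PlacementError(RuntimeError):
    """Raised when an event cannot be placed in the genome."""


def plant_events(
    genome: ToyGenome,
    requests: Sequence[EventRequest],
    seed: int,
    feature_len: int = 400,
) -> tuple[ToyGenome, list[PlantedEvent]]:
    """Plant antigen-generating events; returns a new genome and the truth.

    aeTSA_intron / aeTSA_intergenic events write a unique coding sequence
    into an expressed window of intronic/intergenic space; aeTSA_lncRNA and
    aeTSA_utr write into a (tumor-only) transcript; aeTSA_frameshift and
    TAA_overexpressed take their peptide from existing exonic sequence (in
    shifted and annotated frame respectively); mTSA_snv introduces a
    somatic missense variant whose mutant allele is applied to tumor reads
    only.  Host transcripts are never reused across events.
    """
    rng = np.random.default_rng(seed)
    chroms = {c: s for c, s in genome.chromosomes.items()}
    out = ToyGenome(chroms, genome.annotation, list(genome.germline_snps))
    truth: list[PlantedEvent] = []
    used_hosts: set[str] = set()
    used_windows: list[tuple[str, int, int]] = []
    proteome = canonical_proteins(genome)
    proteome_blob = "|".join(proteome.values())
    peptides_seen: set[str] = set()

    def overlaps_reserved(chrom: str, a: int, b: int) -> bool:
        if any(c == chrom and a <= p < b for c, p, _, _ in out.germline_snps):
            return True
        return any(c == chrom and a < e and s < b for c, s, e in used_windows)

    def fresh_peptide(n: int) -> tuple[str, str]:
        for _ in range(200):
            pep = _random_peptide(rng, n)
            if pep in peptides_seen or pep in proteome_blob:
                continue
            mcs = _encode(rng, pep)
            if _absent(chroms, mcs):
                return pep, mcs
        raise PlacementError("could not draw a unique peptide/coding sequence")

    def write(chrom: str, a: int, seq: str) -> None:
        chroms[chrom] = chroms[chrom][:a] + seq + chroms[chrom][a + len(seq):]

    def free_hosts(predicate) -> list[TranscriptModel]:
        cands = [
            tx
            for tx in genome.annotation
            if tx.transcript_id not in used_hosts and predicate(tx)
        ]
        if not cands:
            raise PlacementError("no eligible host transcript left")
        order = rng.permutation(len(cands))
        return [cands[i] for i in order]

    for req in requests:
        n = req.peptide_length
        if not (8 <= n <= 11):
            raise ValueError("planted peptides must be 8-11 aa")
        depths = dict(
            tumor_depth=req.tumor_depth,
            normal_depth=req.normal_depth,
            mtec_depth=req.mtec_depth,
        )

        if req.kind == "aeTSA_intergenic":
            pep, mcs = fresh_peptide(n)
            placed = False
            for chrom in rng.permutation(list(chroms)):
                occupied = sorted(
                    [(tx.start, tx.end) for tx in genome.annotation if tx.chrom == chrom]
                    + [(s, e) for c, s, e in used_windows if c == chrom]
                )
                gaps, prev = [], 100
                for s, e in occupied:
                    if s - prev >= feature_len + 100:
                        gaps.append((prev, s))
                    prev = max(prev, e)
                if len(chroms[chrom]) - 100 - prev >= feature_len + 100:
                    gaps.append((prev, len(chroms[chrom]) - 100))
                if not gaps:
                    continue
                gs, ge = gaps[int(rng.integers(0, len(gaps)))]
                fstart = gs + 50
                fend = fstart + feature_len
                strand = "+" if rng.random() < 0.5 else "-"
                mid = fstart + (feature_len - len(mcs)) // 2
                write(chrom, mid, mcs if strand == "+" else revcomp(mcs))
                if not _occurs_once(chroms, mcs):
                    raise PlacementError("planted coding sequence not unique")
                used_windows.append((chrom, fstart, fend))
                truth.append(
                    PlantedEvent(
                        req.kind,
                        (chrom, mid, mid + len(mcs), strand),
                        pep,
                        mcs,
                        feature=(chrom, fstart, fend, strand),
                        expected_region="intergenic",
                        **depths,
                    )
                )
                placed = True
                break
            if not placed:
                raise PlacementError("no intergenic space left")

        elif req.kind == "aeTSA_intron":
            pep, mcs = fresh_peptide(n)
            for tx in free_hosts(
                lambda t: t.biotype == "protein_coding" and len(t.exons) >= 2
            ):
                intron = None
                for (a1, b1), (a2, b2) in zip(tx.exons, tx.exons[1:]):
                    if a2 - b1 >= feature_len // 2 + 40 and not overlaps_reserved(
                        tx.chrom, b1, a2
                    ):
                        intron = (b1, a2)
                        break
                if intron is None:
                    continue
                fstart = intron[0] + 10
                fend = min(intron[1] - 10, fstart + feature_len)
                mid = fstart + (fend - fstart - len(mcs)) // 2
                write(tx.chrom, mid, mcs if tx.strand == "+" else revcomp(mcs))
                if not _occurs_once(chroms, mcs):
                    raise PlacementError("planted coding sequence not unique")
                used_windows.append((tx.chrom, fstart, fend))
                used_hosts.add(tx.transcript_id)
                truth.append(
                    PlantedEvent(
                        req.kind,
                        (tx.chrom, mid, mid + len(mcs), tx.strand),
                        pep,
                        mcs,
                        feature=(tx.chrom, fstart, fend, tx.strand),
                        host_transcript_id=tx.transcript_id,
                        expected_region="intron",
                        **depths,
                    )
                )
                break
            else:
                raise PlacementError("no intron wide enough")

        elif req.kind == "aeTSA_lncRNA":
            pep, mcs = fresh_peptide(n)
            tx = free_hosts(lambda t: t.biotype == "lncRNA")[0]
            exon = max(tx.exons, key=lambda ab: ab[1] - ab[0])
            if exon[1] - exon[0] < len(mcs) + 20:
                raise PlacementError("lncRNA exon too short")
            mid = exon[0] + (exon[1] - exon[0] - len(mcs)) // 2
            write(tx.chrom, mid, mcs if tx.strand == "+" else revcomp(mcs))
            if not _occurs_once(chroms, mcs):
                raise PlacementError("planted coding sequence not unique")
            used_hosts.add(tx.transcript_id)
            truth.append(
                PlantedEvent(
                    req.kind,
                    (tx.chrom, mid, mid + len(mcs), tx.strand),
                    pep,
                    mcs,
                    host_transcript_id=tx.transcript_id,
                    expected_region="lncRNA",
                    **depths,
                )
            )

        elif req.kind == "aeTSA_utr":
            pep, mcs = fresh_peptide(n)
            placed = False
            for tx in free_hosts(lambda t: t.cds is not None):
                pos_map = genomic_positions(tx)
                _, ce = tx.cds
                L = tx.spliced_length
                for s in range(ce + 3, L - len(mcs) - 3):
                    if _exonic_window(tx, pos_map, s, s + len(mcs)):
                        gpos = sorted((pos_map[s], pos_map[s + len(mcs) - 1]))
                        a, b = gpos[0], gpos[1] + 1
                        write(tx.chrom, a, mcs if tx.strand == "+" else revcomp(mcs))
                        if not _occurs_once(chroms, mcs):
                            raise PlacementError("planted coding sequence not unique")
                        used_hosts.add(tx.transcript_id)
                        truth.append(
                            PlantedEvent(
                                req.kind,
                                (tx.chrom, a, b, tx.strand),
                                pep,
                                mcs,
                                host_transcript_id=tx.transcript_id,
                                expected_region="UTR3",
                                **depths,
                            )
                        )
                        placed = True
                        break
                if placed:
                    break
            if not placed:
                raise PlacementError("no 3'UTR window available")

        elif req.kind == "aeTSA_frameshift":
            placed = False
            for tx in free_hosts(lambda t: t.cds is not None):
                pos_map = genomic_positions(tx)
                cs, ce = tx.cds
                spliced = out.spliced(tx)
                starts = list(range(cs + 1 + 9, ce - 3 * n - 9, 3))
                rng.shuffle(starts)
                for s in starts:
                    if not _exonic_window(tx, pos_map, s, s + 3 * n):
                        continue
                    mcs = spliced[s : s + 3 * n]
                    pep = translate(mcs)
                    if "*" in pep or pep in proteome_blob or pep in peptides_seen:
                        continue
                    if not _occurs_once(chroms, mcs):
                        continue
                    gpos = sorted((pos_map[s], pos_map[s + 3 * n - 1]))
                    used_hosts.add(tx.transcript_id)
                    truth.append(
                        PlantedEvent(
                            req.kind,
                            (tx.chrom, gpos[0], gpos[1] + 1, tx.strand),
                            pep,
                            mcs,
                            host_transcript_id=tx.transcript_id,
                            expected_region="exon_frameshift",
                            **depths,
                        )
                    )
                    placed = True
                    break
                if placed:
                    break
            if not placed:
                raise PlacementError("no frameshift window available")

        elif req.kind == "mTSA_snv":
            placed = False
            for tx in free_hosts(lambda t: t.cds is not None):
                pos_map = genomic_positions(tx)
                cs, ce = tx.cds
                spliced = out.spliced(tx)
                n_codons = (ce - cs) // 3
                cands = list(range(5, n_codons - n - 5))
                rng.shuffle(cands)
                for c0 in cands:
                    # peptide window: codons c0 .. c0+n-1, mutate middle codon
                    s = cs + 3 * c0
                    if not _exonic_window(tx, pos_map, s, s + 3 * n):
                        continue
                    cmid = c0 + n // 2
                    codon = spliced[cs + 3 * cmid : cs + 3 * cmid + 3]
                    subs = []
                    for off in range(3):
                        for b in "ACGT":
                            if b == codon[off]:
                                continue
                            new = codon[:off] + b + codon[off + 1:]
                            if new not in SENSE_CODONS:
                                continue
                            if translate(new) != translate(codon):
                                subs.append((off, b, new))
                    rng.shuffle(subs)
                    hit = None
                    for off, b, new in subs:
                        mut = spliced[s : cs + 3 * cmid] + new + spliced[cs + 3 * cmid + 3 : s + 3 * n]
                        pep = translate(mut)
                        if pep in proteome_blob or pep in peptides_seen:
                            continue
                        if not _absent(chroms, mut):
                            continue
                        hit = (off, b, new, mut, pep)
                        break
                    if hit is None:
                        continue
                    off, b, new, mut, pep = hit
                    spos = cs + 3 * cmid + off
                    gpos = pos_map[spos]
                    ref_g = chroms[tx.chrom][gpos]
                    alt_g = b if tx.strand == "+" else complement(b)
                    if any(
                        c == tx.chrom and p == gpos for c, p, _, _ in out.germline_snps
                    ):
                        continue
                    span = sorted((pos_map[s], pos_map[s + 3 * n - 1]))
                    used_hosts.add(tx.transcript_id)
                    truth.append(
                        PlantedEvent(
                            req.kind,
                            (tx.chrom, span[0], span[1] + 1, tx.strand),
                            pep,
                            mut,
                            host_transcript_id=tx.transcript_id,
                            snv=(tx.chrom, gpos, ref_g, alt_g),
                            expected_region="exon",
                            **depths,
                        )
                    )
                    placed = True
                    break
                if placed:
                    break
            if not placed:
                raise PlacementError("no mutable codon window available")

        elif req.kind == "TAA_overexpressed":
            placed = False
            for tx in free_hosts(lambda t: t.cds is not None):
                pos_map = genomic_positions(tx)
                cs, ce = tx.cds
                spliced = out.spliced(tx)
                n_codons = (ce - cs) // 3
                starts = list(range(4, n_codons - n - 4))
                rng.shuffle(starts)
                for c0 in starts:
                    s = cs + 3 * c0
                    if not _exonic_window(tx, pos_map, s, s + 3 * n):
                        continue
                    mcs = spliced[s : s + 3 * n]
                    pep = translate(mcs)
                    if "*" in pep or pep in peptides_seen:
                        continue
                    if proteome_blob.count(pep) != 1 or not _occurs_once(chroms, mcs):
                        continue
                    span = sorted((pos_map[s], pos_map[s + 3 * n - 1]))
                    used_hosts.add(tx.transcript_id)
                    truth.append(
                        PlantedEvent(
                            req.kind,
                            (tx.chrom, span[0], span[1] + 1, tx.strand),
                            pep,
                            mcs,
                            host_transcript_id=tx.transcript_id,
                            expected_region="exon",
                            **depths,
                        )
                    )
                    placed = True
                    break
                if placed:
                    break
            if not placed:
                raise PlacementError("no TAA window available")

        else:
            raise ValueError(f"unknown event kind {req.kind!r}")

        peptides_seen.add(truth[-1].expected_peptide)

    out.chromosomes = chroms
    out.validate()
    return out, truth


# ---------------------------------------------------------------------------
# read simulation

FeatureKey = "str | tuple[str, int, int, str]"


def simulate_reads(
    genome: ToyGenome,
    sample_profile: Mapping[object, float],
    read_len: int = 75,
    seed: int = 0,
    sample_id: str = "sample",
    snvs: Sequence[tuple[str, int, str, str]] | None = None,
    antisense_fraction: float = 0.0,
) -> ReadSet:
    """Uniform error-free stranded reads from expressed features.

    Keys of ``sample_profile`` are transcript ids (spliced sequence is
    expressed) or ``(chrom, start0, end0, strand)`` windows.  ``snvs`` are
    applied to the chromosomes before slicing (tumor-personalized reads).
    The number of reads per feature is ``round(depth * len / read_len)``
    with uniformly random start positions.
    """
    chroms = dict(genome.chromosomes)
    for chrom, pos, ref, alt in snvs or ():
        s = chroms[chrom]
        if s[pos] != ref:
            raise ValueError(f"SNV ref mismatch at {chrom}:{pos}")
        chroms[chrom] = s[:pos] + alt + s[pos + 1:]
    patched = ToyGenome(chroms, genome.annotation, genome.germline_snps)

    rng = np.random.default_rng(seed)
    reads: list[str] = []
    for key, depth in sample_profile.items():
        if depth < 0:
            raise ValueError("depths must be >= 0")
        if depth == 0:
            continue
        if isinstance(key, str):
            seq = patched.spliced(patched.transcript(key))
        else:
            chrom, a, b, strand = key
            seq = chroms[chrom][a:b]
            if strand == "-":
                seq = revcomp(seq)
        if len(seq) < read_len:
            raise ValueError(f"feature {key!r} shorter than read length")
        n_reads = int(round(depth * len(seq) / read_len))
        if n_reads == 0:
            continue
        starts = rng.integers(0, len(seq) - read_len + 1, n_reads)
        for st in starts:
            r = seq[st : st + read_len]
            if antisense_fraction and rng.random() < antisense_fraction:
                r = revcomp(r)
            reads.append(r)
    return ReadSet(sample_id, reads, len(reads), stranded=True, read_len=read_len)


# ---------------------------------------------------------------------------
# identification / quantitation table simulation


def simulate_identifications(
    truth: Sequence[PlantedEvent],
    expressed_proteome: Mapping[str, str],
    n_targets: int = 60,
    n_decoys: int = 30,
    seed: int = 0,
    sample_id: str = "tumor",
) -> list[MapRecord]:
    """Search-engine-like MAP table: planted peptides as confident targets,
    canonical fillers, and reversed-sequence decoys with lower scores.

    Filler lengths are drawn in 7-13 aa and ranks occasionally exceed 2%
    so the downstream length/rank filters are exercised.
    """
    planted = [ev.expected_peptide for ev in truth]
    if n_targets < len(planted):
        raise ValueError("n_targets must cover all planted peptides")
    rng = np.random.default_rng(seed)
    records: list[MapRecord] = []
    for ev in truth:
        # overexpressed canonical antigens are hit through the canonical
        # proteome; everything else comes out of the k-mer database
        canonical_origin = ev.expected_label == "TAA"
        records.append(
            MapRecord(
                peptide=ev.expected_peptide,
                sample_id=sample_id,
                score=float(rng.normal(55.0, 3.0)),
                is_decoy=False,
                best_allele="HLA-A*02:01",
                percent_rank=float(rng.uniform(0.05, 1.5)),
                source_accession=(
                    f"canonical|{ev.host_transcript_id}"
                    if canonical_origin
                    else "csdb|planted"
                ),
                db_origin="canonical" if canonical_origin else "cancer_specific",
            )
        )
    headers = sorted(expressed_proteome)
    lengths = [7, 8, 9, 9, 10, 10, 11, 12, 13]
    for _ in range(n_targets - len(planted)):
        h = headers[int(rng.integers(0, len(headers)))]
        prot = expressed_proteome[h]
        ln = lengths[int(rng.integers(0, len(lengths)))]
        st = int(rng.integers(0, max(1, len(prot) - ln)))
        rank = (
            float(rng.uniform(0.05, 2.0))
            if rng.random() < 0.75
            else float(rng.uniform(2.001, 8.0))
        )
        records.append(
            MapRecord(
                peptide=prot[st : st + ln],
                sample_id=sample_id,
                score=float(rng.normal(40.0, 6.0)),
                is_decoy=False,
                best_allele="HLA-A*02:01",
                percent_rank=rank,
                source_accession=h,
                db_origin="canonical",
            )
        )
    targets = [r.peptide for r in records]
    for _ in range(n_decoys):
        src = targets[int(rng.integers(0, len(targets)))]
        records.append(
            MapRecord(
                peptide=src[::-1],
                sample_id=sample_id,
                score=float(rng.normal(20.0, 4.0)),
                is_decoy=True,
                best_allele="HLA-A*02:01",
                percent_rank=float(rng.uniform(0.05, 5.0)),
                source_accession="decoy|" + src,
                db_origin="canonical",
            )
        )
    return records


def simulate_psm_table(
    peptide: str,
    true_ratio: float,
    n_psms: int = 50,
    noise: float = 0.2,
    seed: int = 0,
    sample_id: str = "S1",
    base_normal: float = 100.0,
    contaminated_fraction: float = 0.1,
    labeled_fraction: float = 1.0,
) -> list[PsmQuantRecord]:
    """TMT PSM table with a planted tumor/NAT reporter ratio.

    Each PSM carries a shared log-normal sampling scale (ion-injection
    spread across spectra) on top of which every channel gets independent
    multiplicative log-normal noise of the given sigma; a fraction of PSMs
    gets signal in the nominally empty 127C channel, and synthetic-peptide
    calibration channels (129N/130N/131N) scale 1:10:100.
    """
    rng = np.random.default_rng(seed)
    psms = []
    for i in range(n_psms):
        scale = float(np.exp(rng.normal(0.0, 0.5)))  # per-PSM sampling depth

        def chan(mean: float) -> float:
            return mean * scale * float(np.exp(rng.normal(0.0, noise)))

        contaminated = rng.random() < contaminated_fraction
        channels = {
            "126": chan(base_normal),
            "127N": chan(true_ratio * base_normal),
            "127C": float(rng.uniform(5.0, 50.0)) if contaminated else 0.0,
            "129N": chan(10.0),
            "130N": chan(100.0),
            "131N": chan(1000.0),
        }
        psms.append(
            PsmQuantRecord(
                peptide=peptide,
                sample_id=sample_id,
                channel_intensities=channels,
                is_tmt_labeled=bool(rng.random() < labeled_fraction),
            )
        )
    return psms


def simulate_spectrum_pair(
    peptide: str,
    n_fragments: int = 12,
    scale: float = 4.0,
    noise: float = 0.0,
    seed: int = 0,
) -> SpectrumPair:
    """Endogenous/synthetic fragment-spectrum pair with a known scaling."""
    rng = np.random.default_rng(seed)
    frags = [f"b{i}" for i in range(2, 2 + n_fragments // 2)] + [
        f"y{i}" for i in range(2, 2 + (n_fragments + 1) // 2)
    ]
    endo, synth = [], []
    for j, fid in enumerate(frags):
        mz = 200.0 + 90.0 * j + float(rng.uniform(0, 5))
        inten = float(rng.uniform(1e3, 1e5))
        endo.append((fid, mz, inten))
        jitter = float(np.exp(rng.normal(0.0, noise))) if noise else 1.0
        synth.append((fid, mz, scale * inten * jitter))
    return SpectrumPair(peptide=peptide, endogenous=endo, synthetic=synth)


# ---------------------------------------------------------------------------
# writers (plain-text external interfaces)


def write_fasta(path, entries: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path, readset: ReadSet) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(readset.reads):
            fh.write(f"@{readset.sample_id}.{i}\n{r}\n+\n{'I' * len(r)}\n")


def write_exon_table(path, genome: ToyGenome) -> None:
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\tgene_id\tbiotype\tchrom\tstrand\t"
            "exon_start0\texon_end0\tcds_start\tcds_end\n"
        )
        for tx in genome.annotation:
            cs, ce = tx.cds if tx.cds else ("", "")
            for a, b in tx.exons:
                fh.write(
                    f"{tx.transcript_id}\t{tx.gene_id}\t{tx.biotype}\t{tx.chrom}\t"
                    f"{tx.strand}\t{a}\t{b}\t{cs}\t{ce}\n"
                )


def write_gtf(path, genome: ToyGenome) -> None:
    with open(path, "w") as fh:
        for tx in genome.annotation:
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'biotype "{tx.biotype}";'
            )
            for a, b in tx.exons:
                fh.write(
                    f"{tx.chrom}\ttoy\texon\t{a + 1}\t{b}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


def write_truth(path_tsv, path_json, truth: Sequence[PlantedEvent]) -> None:
    with open(path_tsv, "w") as fh:
        fh.write(
            "kind\texpected_peptide\texpected_label\texpected_region\t"
            "chrom\tstart0\tend0\tstrand\tmcs\ttumor_depth\tnormal_depth\tmtec_depth\n"
        )
        for ev in truth:
            c, s, e, st = ev.locus
            fh.write(
                f"{ev.kind}\t{ev.expected_peptide}\t{ev.expected_label}\t"
                f"{ev.expected_region}\t{c}\t{s}\t{e}\t{st}\t{ev.mcs}\t"
                f"{ev.tumor_depth}\t{ev.normal_depth}\t{ev.mtec_depth}\n"
            )
    with open(path_json, "w") as fh:
        json.dump([dataclasses.asdict(ev) for ev in truth], fh, indent=1, default=list)
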