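"""Cancer-specific peptide database construction by k-mer subtraction.

The proteogenomic database for MHC-peptide searches is the concatenation of
the canonical proteome with a "cancer-specific proteome": RNA-seq reads are
cut into 33-nt k-mers, k-mers seen in the matched normal (NAT or an mTEC
pool) are subtracted, the surviving tumor-restricted k-mers are assembled
into unitig contigs, three-frame translated on the sense strand, and the
resulting short amino-acid fragments are packed into ~10,000-residue
entries joined with the two-character "JJ" separator.

Database-generation counting is non-canonical (stranded libraries); the
24-mer counting used downstream for quantification merges reverse
complements (canonical form).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .seqs import revcomp, translate
from .syndata import ReadSet

_ACGT = frozenset("ACGT")


@dataclass
class KmerSet:
    k: int
    counts: dict[str, int]
    rtot: int  # total reads in the source library
    canonical: bool = False

    def get(self, kmer: str) -> int:
        """Occurrence count of a k-mer, honoring the canonical flag."""
        if self.canonical:
            kmer = min(kmer, revcomp(kmer))
        return self.counts.get(kmer, 0)


@dataclass
class Contig:
    sequence: str
    n_kmers: int


@dataclass
class ProteomeDB:
    entries: list[tuple[str, str]] = field(default_factory=list)
    origins: list[str] = field(default_factory=list)  # canonical | cancer_specific

    def write_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for header, seq in self.entries:
                fh.write(f">{header}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def count_kmers(
    reads: "ReadSet | Sequence[str]", k: int, canonical: bool = False
) -> KmerSet:
    """Sliding-window k-mer counts over a read set.

    K-mers containing non-ACGT characters are skipped.  With
    ``canonical=True`` each k-mer is merged with its reverse complement and
    stored under the lexicographic minimum of the two (Jellyfish -C).
    """
    if isinstance(reads, ReadSet):
        seqs: Sequence[str] = reads.reads
        rtot = reads.total_reads
        if k > reads.read_len:
            raise ValueError("k exceeds read length")
    else:
        seqs = list(reads)
        rtot = len(seqs)
        if seqs and k > max(len(s) for s in seqs):
            raise ValueError("k exceeds read length")

    counts: Counter[str] = Counter()
    for r in seqs:
        counts.update(r[i : i + k] for i in range(len(r) - k + 1))
    clean = {km: c for km, c in counts.items() if not (set(km) - _ACGT)}
    if canonical:
        folded: dict[str, int] = defaultdict(int)
        for km, c in clean.items():
            folded[min(km, revcomp(km))] += c
        clean = dict(folded)
    return KmerSet(k=k, counts=clean, rtot=rtot, canonical=canonical)


def subtract_normal(
    tumor: KmerSet, normals: Sequence[KmerSet], max_count: int = 2
) -> KmerSet:
    """Tumor k-mers whose summed occurrence across normals is < max_count.

    The default ``max_count=2`` keeps k-mers present 0 or 1 times in the
    pooled normal libraries ("present <2"); retained counts are the tumor
    counts.  ``per_sample_max`` semantics are available by passing each
    normal separately and intersecting the results.
    """
    for n in normals:
        if n.k != tumor.k or n.canonical != tumor.canonical:
            raise ValueError("k / canonical flag mismatch between libraries")
    kept = {
        km: c
        for km, c in tumor.counts.items()
        if sum(n.counts.get(km, 0) for n in normals) < max_count
    }
    return KmerSet(k=tumor.k, counts=kept, rtot=tumor.rtot, canonical=tumor.canonical)


def assemble_contigs(kmers: KmerSet) -> list[Contig]:
    """Unitig assembly of a k-mer set on (k-1)-overlaps.

    Maximal non-branching paths of the de Bruijn graph: extension stops at
    any node with in- or out-degree above one.  Every input k-mer ends up
    in exactly one contig; output is sorted lexicographically by sequence.
    Canonical sets are assembled literally on their stored keys.
    """
    if not kmers.counts:
        raise ValueError("empty k-mer set")
    keys = list(kmers.counts)
    by_prefix: dict[str, list[str]] = defaultdict(list)
    by_suffix: dict[str, list[str]] = defaultdict(list)
    for km in keys:
        by_prefix[km[:-1]].append(km)
        by_suffix[km[1:]].append(km)

    def successors(km: str) -> list[str]:
        return by_prefix.get(km[1:], [])

    def predecessors(km: str) -> list[str]:
        return by_suffix.get(km[:-1], [])

    visited: set[str] = set()
    contigs: list[Contig] = []

    def walk(start: str) -> None:
        path = [start]
        visited.add(start)
        cur = start
        while True:
            nxt = successors(cur)
            if len(nxt) != 1:
                break
            nn = nxt[0]
            if nn in visited or len(predecessors(nn)) != 1:
                break
            path.append(nn)
            visited.add(nn)
            cur = nn
        seq = path[0] + "".join(p[-1] for p in path[1:])
        contigs.append(Contig(sequence=seq, n_kmers=len(path)))

    # unitig starts: no unique usable predecessor
    for km in sorted(keys):
        if km in visited:
            continue
        preds = predecessors(km)
        if len(preds) != 1 or len(successors(preds[0])) != 1:
            walk(km)
    # leftover cycles
    for km in sorted(keys):
        if km not in visited:
            walk(km)
    contigs.sort(key=lambda c: c.sequence)
    return contigs


def translate_3frame(
    contig: "Contig | str", min_len: int = 8, both_strands: bool = False
) -> list[str]:
    """Three forward-frame translations split at stop codons.

    Stranded libraries mean only the sense frames are meaningful; set
    ``both_strands=True`` for six-frame translation of unstranded input.
    Fragments shorter than ``min_len`` residues are dropped.
    """
    seq = contig.sequence if isinstance(contig, Contig) else contig
    strands = [seq, revcomp(seq)] if both_strands else [seq]
    frags: list[str] = []
    for s in strands:
        for frame in range(3):
            aa = translate(s[frame:])
            frags.extend(f for f in aa.split("*") if len(f) >= min_len)
    return frags


def build_global_db(
    canonical: Sequence[tuple[str, str]],
    fragments: Sequence[str],
    target_len: int = 10_000,
) -> ProteomeDB:
    """Concatenate canonical proteome and cancer-specific fragments.

    Fragments are greedily packed, in the given order, into entries of at
    most ``target_len`` residues joined with the "JJ" separator; canonical
    entries pass through untouched.
    """
    if not canonical and not fragments:
        raise ValueError("nothing to build: no canonical entries, no fragments")
    db = ProteomeDB()
    for header, seq in canonical:
        db.entries.append((header, seq))
        db.origins.append("canonical")
    current: list[str] = []
    cur_len = 0
    idx = 0

    def flush() -> None:
        nonlocal current, cur_len, idx
        if current:
            idx += 1
            db.entries.append((f"csdb|{idx:04d}", "JJ".join(current)))
            db.origins.append("cancer_specific")
            current, cur_len = [], 0

    for frag in fragments:
        if "J" in frag:
            raise ValueError("fragments must not contain 'J'")
        extra = len(frag) + (2 if current else 0)
        if current and cur_len + extra > target_len:
            flush()
            extra = len(frag)
        current.append(frag)
        cur_len += extra
    flush()
    return db


def split_db_entry(seq: str) -> list[str]:
    """Inverse of the "JJ" concatenation for one cancer-specific entry."""
    return seq.split("JJ")


def write_kmerset(path, kmers: KmerSet) -> None:
    """Two-column TSV, sorted by k-mer, with a one-line metadata header."""
    with open(path, "w") as fh:
        fh.write(f"#k={kmers.k}\tcanonical={int(kmers.canonical)}\trtot={kmers.rtot}\n")
        for km in sorted(kmers.counts):
            fh.write(f"{km}\t{kmers.counts[km]}\n")


def read_kmerset(path) -> KmerSet:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("#")
        meta = dict(kv.split("=") for kv in header.split("\t"))
        counts = {}
        for line in fh:
            km, c = line.split()
            counts[km] = int(c)
    return KmerSet(
        k=int(meta["k"]),
        counts=counts,
        rtot=int(meta["rtot"]),
        canonical=bool(int(meta["canonical"])),
    )
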