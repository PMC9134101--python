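"""Post-processing of MHC-peptide identification tables.

Turns raw search-engine output (targets and reversed-sequence decoys with
scores and predicted eluted-ligand %rank) into a per-sample immunopeptidome:
decoy-based FDR filtering, the 8-11 aa length window, the <=2% binding-rank
cutoff, repertoire comparison by Jaccard index, and source-gene aggregation
in which a gene is counted once per sample regardless of how many peptides
it generates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd


@dataclass
class MapRecord:
    peptide: str
    sample_id: str
    score: float
    is_decoy: bool
    best_allele: str = ""
    percent_rank: float = 0.0
    source_accession: str = ""
    db_origin: str = "canonical"  # canonical | cancer_specific

    def __post_init__(self) -> None:
        if self.percent_rank < 0:
            raise ValueError("percent_rank must be >= 0")


@dataclass
class Immunopeptidome:
    sample_id: str
    peptides: set[str] = field(default_factory=set)
    annotations: dict[str, dict] = field(default_factory=dict)


def fdr_filter(records: Sequence[MapRecord], fdr: float = 0.05) -> list[MapRecord]:
    """Decoy-based FDR filtering at the given rate (default 5%).

    Finds the lowest score threshold t with
    ``(#decoys >= t) / (#targets >= t) <= fdr`` and returns the targets at
    or above it (ties at the threshold are kept).  With no decoys the FDR
    is undefined: a warning is emitted and all targets are returned.
    """
    targets = [r for r in records if not r.is_decoy]
    decoys = [r for r in records if r.is_decoy]
    if not decoys:
        if targets:
            warnings.warn("no decoy records: FDR undefined, returning all targets")
        return list(targets)
    tscores = sorted(r.score for r in targets)
    dscores = sorted(r.score for r in decoys)
    for t in sorted({r.score for r in records}):
        n_t = len(tscores) - _bisect_left(tscores, t)
        n_d = len(dscores) - _bisect_left(dscores, t)
        est = 0.0 if n_d == 0 else (float("inf") if n_t == 0 else n_d / n_t)
        if est <= fdr:
            return [r for r in targets if r.score >= t]
    return []


def _bisect_left(a: list[float], x: float) -> int:
    import bisect

    return bisect.bisect_left(a, x)


def map_filter(
    records: Sequence[MapRecord],
    min_len: int = 8,
    max_len: int = 11,
    max_rank: float = 2.0,
) -> Immunopeptidome:
    """Length (8-11 aa inclusive) and binding-rank (<=2%) filters.

    Records are expected to be FDR-filtered already.  Peptides are
    deduplicated to a set; a peptide seen from both canonical and
    cancer-specific accessions gets ``db_origin='both'`` and keeps the
    union of accessions.  All records must belong to one sample.
    """
    samples = {r.sample_id for r in records}
    if len(samples) > 1:
        raise ValueError("map_filter expects records from a single sample")
    sample_id = samples.pop() if samples else "empty"
    pep = Immunopeptidome(sample_id=sample_id)
    for r in records:
        if r.is_decoy:
            continue
        if not (min_len <= len(r.peptide) <= max_len):
            continue
        if r.percent_rank > max_rank:
            continue
        ann = pep.annotations.get(r.peptide)
        if ann is None:
            pep.peptides.add(r.peptide)
            pep.annotations[r.peptide] = {
                "allele": r.best_allele,
                "accessions": {r.source_accession},
                "db_origin": r.db_origin,
                "score": r.score,
            }
        else:
            ann["accessions"].add(r.source_accession)
            ann["score"] = max(ann["score"], r.score)
            if ann["db_origin"] != r.db_origin:
                ann["db_origin"] = "both"
    return pep


def jaccard(a: Immunopeptidome, b: Immunopeptidome) -> float:
    """|A & B| / |A | B|; 0.0 when both repertoires are empty."""
    union = a.peptides | b.peptides
    if not union:
        return 0.0
    return len(a.peptides & b.peptides) / len(union)


def source_gene_summary(
    peptidomes: Sequence[Immunopeptidome],
    peptide_to_gene: Mapping[str, str],
    min_shared: int = 4,
) -> pd.DataFrame:
    """Per-sample deduplicated source-gene table with sharing counts.

    A gene generating several unique peptides in one sample counts once
    for that sample.  Peptides without a gene mapping are pooled under
    ``unannotated``.  The returned frame has one row per gene, one
    ``n_peptides:<sample>`` column per sample, a ``shared_by`` column, and
    a boolean ``shared_ge_{min_shared}`` selection column.
    """
    rows: dict[str, dict[str, int]] = {}
    for pep in peptidomes:
        for p in pep.peptides:
            gene = peptide_to_gene.get(p, "unannotated")
            rows.setdefault(gene, {}).setdefault(pep.sample_id, 0)
            rows[gene][pep.sample_id] += 1
    if not rows:
        return pd.DataFrame(
            columns=["gene", "shared_by", f"shared_ge_{min_shared}"]
        ).set_index("gene")
    samples = [p.sample_id for p in peptidomes]
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=samples)
    df = df.fillna(0).astype(int)
    df.columns = [f"n_peptides:{s}" for s in df.columns]
    df["shared_by"] = (df > 0).sum(axis=1)
    df[f"shared_ge_{min_shared}"] = df["shared_by"] >= min_shared
    df.index.name = "gene"
    return df.sort_index()


def records_to_frame(records: Iterable[MapRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def frame_to_records(df: pd.DataFrame) -> list[MapRecord]:
    cols = [
        "peptide",
        "sample_id",
        "score",
        "is_decoy",
        "best_allele",
        "percent_rank",
        "source_accession",
        "db_origin",
    ]
    return [MapRecord(**{c: row[c] for c in cols}) for _, row in df.iterrows()]
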