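"""The tumor-specific-antigen identification cascade.

Candidate MHC peptides surviving identification filters are pushed through
a stringent sequence of expression and localization screens before being
labeled:

1. expression gate — the coding sequence must be expressed at least
   ``min_fold`` (10x) higher in cancer than in the matched normal and be
   below ``max_normal_kphm`` (2 KPHM) in that normal;
2. isoleucine/leucine disambiguation — MS cannot distinguish I from L, so
   a candidate is kept only when it is itself the most-expressed I/L
   variant and that variant passes the gate;
3. normal-panel screen — expression must stay under ``max_rphm``
   (8.55 RPHM) in every normal tissue of a GTEx-like panel plus mTECs,
   with an optional exemption for MHC-low tissues (brain, nerve, testis;
   a testis-only signal earns a cancer-testis-antigen annotation);
4. localization screen — candidates with no exact genomic placement, too
   many equally plausible loci, or a placement inside a hypervariable
   region (HLA/Ig/TCR) are excluded; survivors get a genomic region label
   with precedence CDS-exon > UTR > lncRNA exon > intron > intergenic,
   and exon hits off the annotated frame are labeled ``exon_frameshift``;
5. final label — mTSA when the peptide differs from the reference
   translation at its locus through a non-germline variant; otherwise
   aeTSA when mTEC (and NAT, for tissues) expression is <= 0.2 KPHM; TAA
   when the 10-fold overexpression holds but mTEC/NAT expression exceeds
   0.2 KPHM; excluded otherwise.

All thresholds are per-10^8-read normalized units and are exposed as
parameters; defaults are the study-scale values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .mcsquant import McsHit
from .seqs import translate, revcomp
from .syndata import ToyGenome, TranscriptModel, genomic_positions

REGIONS = (
    "exon",
    "exon_frameshift",
    "UTR5",
    "UTR3",
    "lncRNA",
    "intron",
    "intergenic",
)

_PRECEDENCE = {r: i for i, r in enumerate(REGIONS)}

MHC_LOW_TISSUES = frozenset({"brain", "nerve", "testis"})


@dataclass
class AntigenCall:
    peptide: str
    sample_id: str
    label: str  # mTSA | aeTSA | TAA | excluded
    exclusion_reason: str | None = None
    region: str | None = None
    source_transcript_id: str | None = None
    fold_change_cancer_vs_normal: float = 0.0
    mtec_kphm: float = 0.0
    nat_kphm: float = 0.0
    max_normal_rphm: float = 0.0
    cta_flag: bool = False

    def __post_init__(self) -> None:
        if (self.label == "excluded") != (self.exclusion_reason is not None):
            raise ValueError("exclusion_reason set iff label == excluded")


@dataclass
class NormalPanel:
    rphm: dict[str, float]
    mhc_low_tissues: frozenset[str] = MHC_LOW_TISSUES

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.rphm.values()):
            raise ValueError("rphm values must be >= 0")


@dataclass
class GateResult:
    passed: bool
    fold: float  # inf sentinel when normal expression is zero
    cancer_kphm: float
    normal_kphm: float


def expression_gate(
    cancer_kphm: float,
    normal_kphm: float,
    min_fold: float = 10.0,
    max_normal_kphm: float = 2.0,
) -> GateResult:
    """>=10-fold cancer/normal overexpression with normal < 2 KPHM.

    The rule is multiplicative, so zero normal expression with any cancer
    expression passes with an infinite fold change (no pseudocounts).
    """
    if cancer_kphm <= 0:
        return GateResult(False, 0.0, cancer_kphm, normal_kphm)
    fold = math.inf if normal_kphm == 0 else cancer_kphm / normal_kphm
    passed = normal_kphm < max_normal_kphm and cancer_kphm >= min_fold * normal_kphm
    return GateResult(passed, fold, cancer_kphm, normal_kphm)


def il_variants(peptide: str, cap: int = 10) -> list[str]:
    """All I<->L substitution variants of a peptide (including itself).

    With more than ``cap`` I/L residues the full 2^m enumeration is
    truncated to single-substitution variants, with a warning.
    """
    positions = [i for i, aa in enumerate(peptide) if aa in "IL"]
    if not positions:
        return [peptide]
    if len(positions) > cap:
        warnings.warn(
            f"{len(positions)} I/L residues: enumerating single substitutions only"
        )
        out = [peptide]
        for i in positions:
            sub = "L" if peptide[i] == "I" else "I"
            out.append(peptide[:i] + sub + peptide[i + 1 :])
        return out
    out = []
    for mask in range(2 ** len(positions)):
        chars = list(peptide)
        for b, i in enumerate(positions):
            if mask >> b & 1:
                chars[i] = "L" if peptide[i] == "I" else "I"
        out.append("".join(chars))
    return out


def il_disambiguate(
    peptide: str,
    variant_cancer_kphm: Mapping[str, float],
    candidate_gate: GateResult,
) -> bool:
    """Keep the candidate iff it is the most-expressed I/L variant and the
    gate passes for it.

    ``variant_cancer_kphm`` maps each variant (including the candidate) to
    its cancer expression; ties in favor of the candidate.
    """
    if peptide not in variant_cancer_kphm:
        raise ValueError("candidate missing from variant expression map")
    top = max(variant_cancer_kphm.values())
    if variant_cancer_kphm[peptide] < top:
        return False
    return candidate_gate.passed


@dataclass
class ScreenResult:
    passed: bool
    failing_tissues: list[str] = field(default_factory=list)
    cta_flag: bool = False


def normal_screen(
    panel: NormalPanel,
    max_rphm: float = 8.55,
    exempt_mhc_low: bool = False,
) -> ScreenResult:
    """Strict ``rphm < max_rphm`` in every normal-panel tissue.

    With ``exempt_mhc_low`` the MHC-low tissues may exceed the threshold
    without failing the screen; an above-threshold testis then flags the
    candidate as a potential cancer-testis antigen.
    """
    if not panel.rphm:
        raise ValueError("normal panel is empty")
    failing = [t for t, v in panel.rphm.items() if v >= max_rphm]
    if exempt_mhc_low:
        hard = [t for t in failing if t not in panel.mhc_low_tissues]
        cta = "testis" in failing and not hard
        return ScreenResult(passed=not hard, failing_tissues=failing, cta_flag=cta)
    return ScreenResult(passed=not failing, failing_tissues=failing)


@dataclass
class LocalizationResult:
    passed: bool
    region: str | None = None
    reason: str | None = None
    top_hit: McsHit | None = None


def _spliced_index(tx: TranscriptModel) -> dict[int, int]:
    return {g: i for i, g in enumerate(genomic_positions(tx))}


def _region_for_hit(hit: McsHit, annotation: Sequence[TranscriptModel]) -> str:
    best = "intergenic"
    for tx in annotation:
        if tx.chrom != hit.chrom or tx.strand != hit.strand:
            continue
        if hit.end0 <= tx.start or hit.start0 >= tx.end:
            continue
        idx = _spliced_index(tx)
        inside = [idx.get(g) for g in range(hit.start0, hit.end0)]
        label = "intron"
        if all(i is not None for i in inside):
            spos = sorted(inside)
            s, e = spos[0], spos[-1] + 1
            if tx.cds is None:
                # exonic hit on a transcript without an ORF; the closest
                # region class for any non-coding exon is the lncRNA bucket
                label = "lncRNA"
            else:
                cs, ce = tx.cds
                if e <= cs:
                    label = "UTR5"
                elif s >= ce:
                    label = "UTR3"
                elif s >= cs and e <= ce:
                    label = "exon" if (s - cs) % 3 == 0 else "exon_frameshift"
                else:
                    label = "exon_frameshift"  # straddles a CDS boundary
        if _PRECEDENCE[label] < _PRECEDENCE[best]:
            best = label
    return best


def localization_screen(
    hits: Sequence[McsHit],
    annotation: Sequence[TranscriptModel],
    hypervariable_loci: Sequence[tuple[str, int, int]] = (),
    max_loci: int = 5,
    hit_weights: Mapping[int, float] | None = None,
) -> LocalizationResult:
    """Exclude unclear or hypervariable placements; label the region.

    Fails with no hits, with more than ``max_loci`` distinct loci
    (operationalizing "unclear genomic localization"), or when any hit
    falls inside a configured hypervariable interval (HLA/Ig/TCR stand-in).
    The region is assigned at the top-expressed locus (``hit_weights``
    maps hit indices to expression; default: first hit).
    """
    if not hits:
        return LocalizationResult(False, reason="no_genomic_hit")
    loci = {(h.chrom, h.start0, h.end0, h.strand) for h in hits}
    if len(loci) > max_loci:
        return LocalizationResult(False, reason="ambiguous_localization")
    for h in hits:
        for chrom, a, b in hypervariable_loci:
            if h.chrom == chrom and h.start0 < b and a < h.end0:
                return LocalizationResult(False, reason="hypervariable_region")
    if hit_weights:
        top = hits[max(hit_weights, key=lambda i: hit_weights[i])]
    else:
        top = hits[0]
    region = _region_for_hit(top, annotation)
    return LocalizationResult(True, region=region, top_hit=top)


def is_reference_peptide(
    hit: McsHit, genome: ToyGenome, germline_snps: Sequence[tuple[str, int, str, str]] = ()
) -> tuple[bool, bool]:
    """(matches_reference, differs_only_by_germline) for the hit's MCS.

    The coding sequence is compared base-by-base with the reference genome
    at its locus; mismatches explained entirely by listed germline SNPs do
    not make a peptide tumor-specific.
    """
    if hit.spliced and hit.segments:
        ref = "".join(genome.chromosomes[hit.chrom][a:b] for a, b in hit.segments)
    else:
        ref = genome.chromosomes[hit.chrom][hit.start0 : hit.end0]
    obs = hit.mcs if hit.strand == "+" else revcomp(hit.mcs)
    if obs == ref:
        return True, False
    positions = range(hit.start0, hit.end0)
    germ = {(c, p): (r, a) for c, p, r, a in germline_snps}
    all_germline = True
    for gpos, (rb, ob) in zip(positions, zip(ref, obs)):
        if rb == ob:
            continue
        entry = germ.get((hit.chrom, gpos))
        if entry is None or entry[1] != ob:
            all_germline = False
            break
    return False, all_germline


def final_label(
    peptide: str,
    sample_id: str,
    gate: GateResult,
    is_mutated: bool,
    is_germline: bool,
    mtec_kphm: float,
    nat_kphm: float = 0.0,
    aetsa_max: float = 0.2,
    mode: str = "tissue",
    region: str | None = None,
    source_transcript_id: str | None = None,
    max_normal_rphm: float = 0.0,
    cta_flag: bool = False,
) -> AntigenCall:
    """mTSA / aeTSA / TAA / excluded for one (peptide, sample).

    The aeTSA boundary is inclusive (<= 0.2 KPHM) and the TAA boundary
    exclusive (> 0.2 KPHM); in ``cell_line`` mode the NAT condition is not
    applied.  A germline-explained variant is not an mTSA and falls
    through to the aeTSA/TAA tests.
    """
    common = dict(
        region=region,
        source_transcript_id=source_transcript_id,
        fold_change_cancer_vs_normal=gate.fold,
        mtec_kphm=mtec_kphm,
        nat_kphm=nat_kphm,
        max_normal_rphm=max_normal_rphm,
        cta_flag=cta_flag,
    )
    if is_mutated and not is_germline and gate.passed:
        return AntigenCall(peptide, sample_id, "mTSA", **common)
    if not gate.passed:
        return AntigenCall(
            peptide, sample_id, "excluded", exclusion_reason="expression_gate", **common
        )
    normals_low = mtec_kphm <= aetsa_max and (mode != "tissue" or nat_kphm <= aetsa_max)
    if normals_low:
        return AntigenCall(peptide, sample_id, "aeTSA", **common)
    return AntigenCall(peptide, sample_id, "TAA", **common)


@dataclass
class SourceTranscript:
    transcript_id: str | None
    biotype: str
    tie: bool = False
    n_candidates: int = 0


def assign_source_transcript(
    hit: McsHit,
    annotation: Sequence[TranscriptModel],
    transcript_tpm: Mapping[str, float],
    region: str | None = None,
) -> SourceTranscript:
    """Most highly expressed transcript overlapping the chosen locus.

    Ties pick the lexicographically smallest id and are flagged; with no
    overlapping transcript the biotype falls back to the region label
    ('unannotated' for intergenic hits).  ``n_candidates`` supports the
    analysis mode that excludes peptides with several putative sources.
    """
    cands = [
        tx
        for tx in annotation
        if tx.chrom == hit.chrom
        and tx.strand == hit.strand
        and hit.start0 < tx.end
        and tx.start < hit.end0
    ]
    if not cands:
        return SourceTranscript(None, region or "unannotated", n_candidates=0)
    best_tpm = max(transcript_tpm.get(tx.transcript_id, 0.0) for tx in cands)
    top = sorted(
        tx.transcript_id
        for tx in cands
        if transcript_tpm.get(tx.transcript_id, 0.0) == best_tpm
    )
    chosen = next(tx for tx in cands if tx.transcript_id == top[0])
    return SourceTranscript(
        chosen.transcript_id,
        chosen.biotype,
        tie=len(top) > 1,
        n_candidates=len(cands),
    )


def classify_peptide(
    peptide: str,
    sample_id: str,
    hits: Sequence[McsHit],
    cancer_kphm: float,
    normal_kphm: float,
    mtec_kphm: float,
    nat_kphm: float,
    panel: NormalPanel,
    reference_genome: ToyGenome,
    annotation: Sequence[TranscriptModel],
    transcript_tpm: Mapping[str, float] | None = None,
    variant_cancer_kphm: Mapping[str, float] | None = None,
    min_fold: float = 10.0,
    max_normal_kphm: float = 2.0,
    aetsa_max: float = 0.2,
    max_rphm: float = 8.55,
    mode: str = "tissue",
    hypervariable_loci: Sequence[tuple[str, int, int]] = (),
    exempt_mhc_low: bool = False,
) -> AntigenCall:
    """Run the full cascade for one candidate peptide in one sample."""
    gate = expression_gate(cancer_kphm, normal_kphm, min_fold, max_normal_kphm)
    variant_map = dict(variant_cancer_kphm or {peptide: cancer_kphm})
    variant_map.setdefault(peptide, cancer_kphm)

    def excl(reason: str, **kw) -> AntigenCall:
        return AntigenCall(
            peptide,
            sample_id,
            "excluded",
            exclusion_reason=reason,
            fold_change_cancer_vs_normal=gate.fold,
            mtec_kphm=mtec_kphm,
            nat_kphm=nat_kphm,
            **kw,
        )

    if not gate.passed:
        return excl("expression_gate")
    if not il_disambiguate(peptide, variant_map, gate):
        return excl("il_variant_more_expressed")
    screen = normal_screen(panel, max_rphm=max_rphm, exempt_mhc_low=exempt_mhc_low)
    max_panel = max(panel.rphm.values())
    if not screen.passed:
        return excl("normal_panel_expression", max_normal_rphm=max_panel)
    loc = localization_screen(hits, annotation, hypervariable_loci)
    if not loc.passed:
        return excl(loc.reason or "localization", max_normal_rphm=max_panel)
    matches_ref, germline_only = is_reference_peptide(
        loc.top_hit, reference_genome, reference_genome.germline_snps
    )
    src = assign_source_transcript(
        loc.top_hit, annotation, transcript_tpm or {}, region=loc.region
    )
    return final_label(
        peptide,
        sample_id,
        gate,
        is_mutated=not matches_ref,
        is_germline=germline_only,
        mtec_kphm=mtec_kphm,
        nat_kphm=nat_kphm,
        aetsa_max=aetsa_max,
        mode=mode,
        region=loc.region,
        source_transcript_id=src.transcript_id,
        max_normal_rphm=max_panel,
        cta_flag=screen.cta_flag,
    )
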