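"""End-to-end synthetic tumor/normal study driver.

Wires the whole discovery pipeline together on a generated toy study:
genome + planted events -> stranded read sets (tumor, matched NAT, mTEC
pool, a small GTEx-like normal panel) -> cancer-specific database by 33-mer
subtraction -> simulated identification table -> FDR/length/rank filters ->
MCS mapping and KPHM/RPHM quantification -> the classification cascade.
The planted truth makes the run a parameter-recovery experiment.

Threshold scale: the cascade thresholds (2 / 0.2 KPHM, 8.55 RPHM) are
per-1e8-read quantities calibrated for ~2e8-read libraries.  The toy
libraries hold ~1e4-1e5 reads, where a single detected k-mer already maps
to thousands of KPHM, so the study states its cutoffs as raw
minimum-occurrence / read counts and converts them exactly to the KPHM /
RPHM scale through kphm = kmin * 1e8 / rtot (see docs/methods.md for the
Poisson sizing analysis behind the chosen values).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from . import classify, kmerdb, mapfilter, mcsquant, syndata
from .classify import AntigenCall, NormalPanel
from .kmerdb import KmerSet, ProteomeDB
from .mapfilter import Immunopeptidome
from .mcsquant import ExpressionProfile
from .syndata import EventRequest, PlantedEvent, ReadSet, ToyGenome

PANEL_TISSUES = ("colon_transverse", "liver", "esophagus")


def default_event_requests() -> list[EventRequest]:
    """The stated study: six aeTSAs across intronic/intergenic/lncRNA/UTR
    origins at 20x tumor-only depth, one somatic-SNV mTSA, and two
    canonical TAAs overexpressed 120-fold over a low normal baseline."""
    ae = dict(tumor_depth=20.0, normal_depth=0.0, mtec_depth=0.0)
    return [
        EventRequest("aeTSA_intergenic", 9, **ae),
        EventRequest("aeTSA_intergenic", 10, **ae),
        EventRequest("aeTSA_intron", 9, **ae),
        EventRequest("aeTSA_intron", 11, **ae),
        EventRequest("aeTSA_lncRNA", 9, **ae),
        EventRequest("aeTSA_utr", 9, **ae),
        EventRequest("mTSA_snv", 9, **ae),
        EventRequest(
            "TAA_overexpressed", 9, tumor_depth=1200.0, normal_depth=10.0,
            mtec_depth=10.0,
        ),
        EventRequest(
            "TAA_overexpressed", 9, tumor_depth=1200.0, normal_depth=10.0,
            mtec_depth=10.0,
        ),
    ]


@dataclass
class StudyConfig:
    n_chrom: int = 2
    chrom_len: int = 50_000
    n_genes: int = 10
    n_lncrna: int = 2
    read_len: int = 75
    background_depth: float = 150.0  # shared expression keeping libraries comparable
    n_targets: int = 60
    n_decoys: int = 30
    fdr: float = 0.05
    min_fold: float = 10.0
    # toy-scale cutoffs in raw count units (converted exactly via rtot)
    gate_max_normal_kmin: float = 60.0
    aetsa_max_kmin: float = 0.5
    panel_max_reads: float = 0.5
    requests: list[EventRequest] = field(default_factory=default_event_requests)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        """Load a study configuration from a flat YAML mapping.

        Event requests are given under ``requests`` as mappings with the
        EventRequest fields; omitted keys keep their defaults.
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "requests" in raw:
            raw["requests"] = [EventRequest(**r) for r in raw["requests"]]
        return cls(**raw)


@dataclass
class StudyResult:
    config: StudyConfig
    seed: int
    genome: ToyGenome  # reference (aeTSA loci are reference sequence)
    tumor_genome: ToyGenome  # reference with somatic SNVs applied
    truth: list[PlantedEvent]
    readsets: dict[str, ReadSet]
    cancer_specific_db: ProteomeDB
    cancer_fragments: list[str]
    immunopeptidome: Immunopeptidome
    profiles: dict[str, ExpressionProfile]
    calls: dict[str, AntigenCall]
    thresholds: dict[str, float]


def _child(seed: int, i: int) -> int:
    return (seed * 1_000_003 + 7919 * i + 1) % 2**31


def run_study(seed: int, config: StudyConfig | None = None) -> StudyResult:
    cfg = config or StudyConfig()
    genome = syndata.make_toy_genome(
        _child(seed, 0), cfg.n_chrom, cfg.chrom_len, cfg.n_genes, cfg.n_lncrna
    )
    planted_genome, truth = syndata.plant_events(genome, cfg.requests, _child(seed, 1))

    snvs = [ev.snv for ev in truth if ev.snv]
    tumor_only_hosts = {
        ev.host_transcript_id
        for ev in truth
        if ev.kind in ("aeTSA_utr", "aeTSA_lncRNA", "aeTSA_frameshift")
        and ev.host_transcript_id
    }
    taa_events = [ev for ev in truth if ev.kind == "TAA_overexpressed"]
    mtsa_events = [ev for ev in truth if ev.kind == "mTSA_snv"]
    special = tumor_only_hosts | {
        ev.host_transcript_id for ev in taa_events + mtsa_events
    }
    background = [
        tx.transcript_id
        for tx in planted_genome.annotation
        if tx.transcript_id not in special
    ]

    def profile(kind: str) -> dict:
        prof: dict[object, float] = {t: cfg.background_depth for t in background}
        for ev in mtsa_events:
            prof[ev.host_transcript_id] = ev.tumor_depth
        if kind == "tumor":
            for ev in truth:
                if ev.feature is not None:
                    prof[ev.feature] = ev.tumor_depth
                elif ev.kind not in ("mTSA_snv",):
                    prof[ev.host_transcript_id] = ev.tumor_depth
        elif kind in ("nat", "mtec"):
            depth_attr = "normal_depth" if kind == "nat" else "mtec_depth"
            for ev in taa_events:
                prof[ev.host_transcript_id] = getattr(ev, depth_attr)
        # panel tissues: background + mTSA host reference allele only
        return prof

    readsets = {
        "tumor": syndata.simulate_reads(
            planted_genome, profile("tumor"), cfg.read_len, _child(seed, 2),
            "tumor", snvs=snvs,
        ),
        "nat": syndata.simulate_reads(
            planted_genome, profile("nat"), cfg.read_len, _child(seed, 3), "nat"
        ),
        "mtec": syndata.simulate_reads(
            planted_genome, profile("mtec"), cfg.read_len, _child(seed, 4), "mtec"
        ),
    }
    for i, tissue in enumerate(PANEL_TISSUES):
        readsets[tissue] = syndata.simulate_reads(
            planted_genome, profile("panel"), cfg.read_len, _child(seed, 5 + i), tissue
        )

    # --- cancer-specific database: 33-mer subtraction, contigs, 3-frame ---
    tumor33 = kmerdb.count_kmers(readsets["tumor"], 33, canonical=False)
    nat33 = kmerdb.count_kmers(readsets["nat"], 33, canonical=False)
    specific = kmerdb.subtract_normal(tumor33, [nat33], max_count=2)
    fragments: list[str] = []
    if specific.counts:
        contigs = kmerdb.assemble_contigs(specific)
        for contig in contigs:
            fragments.extend(kmerdb.translate_3frame(contig, min_len=8))
    proteins = syndata.canonical_proteins(planted_genome)
    canonical_entries = sorted(proteins.items())
    db = kmerdb.build_global_db(canonical_entries, fragments)

    # --- 24-mer quantification databases (canonical counting) ---
    k24 = {
        s: kmerdb.count_kmers(readsets[s], 24, canonical=True)
        for s in ("tumor", "nat", "mtec")
    }

    # --- identification table and MAP filters ---
    tx_by_id = {tx.transcript_id: tx for tx in planted_genome.annotation}
    normal_expressed = {
        f"canonical|{tid}": proteins[tx_by_id[tid].gene_id]
        for tid in background + [ev.host_transcript_id for ev in taa_events + mtsa_events]
        if tx_by_id[tid].cds is not None
    }
    records = syndata.simulate_identifications(
        truth, normal_expressed, cfg.n_targets, cfg.n_decoys, _child(seed, 10)
    )
    surviving = mapfilter.fdr_filter(records, cfg.fdr)
    peptidome = mapfilter.map_filter(surviving)

    # --- quantification and classification ---
    tumor_genome = ToyGenome(dict(planted_genome.chromosomes),
                             planted_genome.annotation,
                             planted_genome.germline_snps)
    for chrom, pos, ref, alt in snvs:
        s = tumor_genome.chromosomes[chrom]
        assert s[pos] == ref
        tumor_genome.chromosomes[chrom] = s[:pos] + alt + s[pos + 1:]

    rtots = {s: rs.total_reads for s, rs in readsets.items()}
    thresholds = {
        "max_normal_kphm": cfg.gate_max_normal_kmin * 1e8 / rtots["nat"],
        "aetsa_max": cfg.aetsa_max_kmin * 1e8 / max(rtots["nat"], rtots["mtec"]),
        "max_rphm": cfg.panel_max_reads * 1e8 / max(rtots[t] for t in PANEL_TISSUES),
    }
    tpm = {t: d for t, d in profile("tumor").items() if isinstance(t, str)}

    profiles: dict[str, ExpressionProfile] = {}
    calls: dict[str, AntigenCall] = {}
    panel_sets = {t: readsets[t] for t in PANEL_TISSUES}

    def cancer_kphm_of(pep: str) -> tuple[list, float]:
        hits = mcsquant.map_mcs(pep, tumor_genome)
        if not hits:
            return hits, 0.0
        _, kphm = mcsquant.kphm_quantify(pep, {h.mcs for h in hits}, k24["tumor"])
        return hits, kphm

    for pep in sorted(peptidome.peptides):
        hits = mcsquant.map_mcs(pep, tumor_genome)
        prof = mcsquant.profile_peptide(pep, hits, k24, panel_sets)
        profiles[pep] = prof
        gate = classify.expression_gate(
            prof.kphm("tumor"), prof.kphm("nat"),
            cfg.min_fold, thresholds["max_normal_kphm"],
        )
        variant_map = {pep: prof.kphm("tumor")}
        if gate.passed:
            for var in classify.il_variants(pep):
                if var != pep:
                    variant_map[var] = cancer_kphm_of(var)[1]
        panel = NormalPanel({t: prof.rphm(t) for t in PANEL_TISSUES})
        calls[pep] = classify.classify_peptide(
            pep,
            peptidome.sample_id,
            hits,
            cancer_kphm=prof.kphm("tumor"),
            normal_kphm=prof.kphm("nat"),
            mtec_kphm=prof.kphm("mtec"),
            nat_kphm=prof.kphm("nat"),
            panel=panel,
            reference_genome=planted_genome,
            annotation=planted_genome.annotation,
            transcript_tpm=tpm,
            variant_cancer_kphm=variant_map,
            min_fold=cfg.min_fold,
            max_normal_kphm=thresholds["max_normal_kphm"],
            aetsa_max=thresholds["aetsa_max"],
            max_rphm=thresholds["max_rphm"],
            mode="tissue",
        )

    return StudyResult(
        config=cfg,
        seed=seed,
        genome=planted_genome,
        tumor_genome=tumor_genome,
        truth=truth,
        readsets=readsets,
        cancer_specific_db=db,
        cancer_fragments=fragments,
        immunopeptidome=peptidome,
        profiles=profiles,
        calls=calls,
        thresholds=thresholds,
    )


@dataclass
class RecoverySummary:
    n_events: int
    n_correct_label: int
    n_correct_region: int
    mislabeled: list[tuple[str, str, str]]  # (peptide, expected, got)
    canonical_tsa_labels: list[str]  # non-planted peptides labeled as TSA

    @property
    def all_recovered(self) -> bool:
        return self.n_correct_label == self.n_events and not self.canonical_tsa_labels


def recovery_summary(result: StudyResult) -> RecoverySummary:
    """Compare cascade output with the planted truth."""
    planted = {ev.expected_peptide: ev for ev in result.truth}
    n_correct = 0
    n_region = 0
    mislabeled = []
    for pep, ev in planted.items():
        call = result.calls.get(pep)
        got = call.label if call else "missing"
        if got == ev.expected_label:
            n_correct += 1
        else:
            mislabeled.append((pep, ev.expected_label, got))
        if call and call.region == ev.expected_region:
            n_region += 1
    tsa_labels = [
        pep
        for pep, call in result.calls.items()
        if pep not in planted and call.label in ("aeTSA", "mTSA")
    ]
    return RecoverySummary(
        n_events=len(planted),
        n_correct_label=n_correct,
        n_correct_region=n_region,
        mislabeled=mislabeled,
        canonical_tsa_labels=tsa_labels,
    )
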