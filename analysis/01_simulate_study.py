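#!/usr/bin/env python
"""Generate the synthetic tumor/normal study and export its artifacts.

Builds the toy genome, plants the default antigen-generating events
(six aberrantly expressed TSAs, one somatic-SNV mTSA, two overexpressed
TAAs), simulates stranded read sets for tumor / matched NAT / mTEC pool /
three normal-panel tissues, and writes the genome (FASTA), annotation
(GTF + flat exon TSV), truth (TSV + JSON) under results/ and the read
sets (FASTQ) under scratch/.
"""

import argparse
from pathlib import Path

from tsakit.pipeline import run_study
from tsakit.syndata import (
    write_exon_table,
    write_fasta,
    write_fastq,
    write_gtf,
    write_truth,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", type=Path, default=Path("results/study"))
    ap.add_argument("--scratch", type=Path, default=Path("scratch/reads"))
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)
    args.scratch.mkdir(parents=True, exist_ok=True)

    result = run_study(args.seed)
    genome = result.genome
    write_fasta(args.results / "genome.fasta", genome.chromosomes.items())
    write_gtf(args.results / "annotation.gtf", genome)
    write_exon_table(args.results / "exons.tsv", genome)
    write_truth(args.results / "truth.tsv", args.results / "truth.json", result.truth)
    for name, rs in result.readsets.items():
        write_fastq(args.scratch / f"{name}.fastq", rs)

    print(f"genome: {sum(len(s) for s in genome.chromosomes.values())} nt over "
          f"{len(genome.chromosomes)} chromosomes, "
          f"{len(genome.annotation)} transcripts")
    print(f"planted events ({len(result.truth)}):")
    for ev in result.truth:
        print(f"  {ev.kind:20s} {ev.expected_peptide:12s} expect "
              f"{ev.expected_label}/{ev.expected_region}")
    for name, rs in result.readsets.items():
        print(f"reads[{name}]: {rs.total_reads}")
    print(f"wrote study tables to {args.results}/ and reads to {args.scratch}/")


if __name__ == "__main__":
    main()
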