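#!/usr/bin/env python
"""Build the global cancer database by 33-mer subtraction.

Counts tumor and matched-normal 33-mers, keeps tumor k-mers seen fewer
than twice in the normal, assembles the survivors into unitig contigs,
three-frame translates them, and packs the fragments with the canonical
proteome into the searchable global database ("JJ"-separated entries).
Reports how many planted non-canonical antigens reach the database.
"""

import argparse
from pathlib import Path

from tsakit import kmerdb
from tsakit.pipeline import run_study


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", type=Path, default=Path("results/database"))
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)

    result = run_study(args.seed)
    tumor33 = kmerdb.count_kmers(result.readsets["tumor"], 33)
    nat33 = kmerdb.count_kmers(result.readsets["nat"], 33)
    specific = kmerdb.subtract_normal(tumor33, [nat33], max_count=2)
    contigs = kmerdb.assemble_contigs(specific)
    print(f"tumor 33-mers: {len(tumor33.counts)}; after NAT subtraction: "
          f"{len(specific.counts)} "
          f"({100 * len(specific.counts) / len(tumor33.counts):.1f}% kept)")
    print(f"contigs: {len(contigs)} (longest {max(len(c.sequence) for c in contigs)} nt)")
    print(f"translation fragments (>=8 aa): {len(result.cancer_fragments)}")

    db = result.cancer_specific_db
    db.write_fasta(args.results / "global_db.fasta")
    kmerdb.write_kmerset(args.results / "cancer_specific_33mers.tsv", specific)
    blob = "|".join(seq for _, seq in db.entries)
    n_in = sum(
        ev.expected_peptide in blob
        for ev in result.truth
        if ev.expected_label != "TAA"
    )
    n_expected = sum(1 for ev in result.truth if ev.expected_label != "TAA")
    print(f"planted non-canonical antigen peptides present in database: "
          f"{n_in}/{n_expected}")
    print(f"wrote {args.results}/global_db.fasta "
          f"({sum(1 for o in db.origins if o == 'canonical')} canonical + "
          f"{sum(1 for o in db.origins if o == 'cancer_specific')} cancer-specific entries)")


if __name__ == "__main__":
    main()
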