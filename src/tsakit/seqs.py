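"""Nucleotide/peptide helpers shared across the toolkit.

The genetic code is taken from Biopython's standard table (NCBI table 1).
Only uppercase A/C/G/T sequences are handled; callers are expected to
validate their inputs.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid, stop codons mapped to '*'
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))

#: amino acid -> sorted list of codons (no stops)
BACK_TABLE: dict[str, list[str]] = {}
for _codon, _aa in _TABLE.forward_table.items():
    BACK_TABLE.setdefault(_aa, []).append(_codon)
for _aa in BACK_TABLE:
    BACK_TABLE[_aa].sort()

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(BACK_TABLE))

_RC = str.maketrans("ACGTN", "TGCAN")

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T", frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W", frozenset("GT"): "K",
    frozenset("AC"): "M", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T(/N) string."""
    return seq.translate(_RC)[::-1]


def complement(base: str) -> str:
    return base.translate(_RC)


def translate(nt: str) -> str:
    """Translate ``nt`` in frame 0; stops appear as '*'.

    Trailing bases that do not fill a codon are ignored; codons with
    non-ACGT characters translate to 'X'.
    """
    return "".join(
        CODON_TO_AA.get(nt[i : i + 3], "X") for i in range(0, len(nt) - 2, 3)
    )


def iupac_codon(aa: str) -> str:
    """Positional IUPAC representation of all codons for one residue.

    Note this is a per-position summary: for six-codon residues (L, R, S)
    it covers a superset of the true codon set, so it is a display/compact
    form only; exact matching uses the codon lists themselves.
    """
    codons = BACK_TABLE[aa]
    return "".join(
        _IUPAC[frozenset(c[i] for c in codons)] for i in range(3)
    )
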