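"""Intertumoral sharing of antigen coding sequences across a cohort.

Expression of each peptide-coding sequence is tabulated as RPHM across
tumor columns and a normal baseline (GTEx-like panel plus mTECs).  The
baseline is the mean of log(rphm+1) over the baseline columns,
back-transformed to the rphm scale, and a peptide is "shared" when at
least ``min_frac`` (5%) of tumors express it at least ``min_fold`` (10x)
above that baseline.  Log base 10 by default; the fold comparison runs on
the linear rphm scale (a log-scale option exists since the source
arithmetic is a convention choice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SAMPLE_CLASSES = ("tumor", "normal_panel", "mtec")


@dataclass
class CohortMatrix:
    rphm: pd.DataFrame  # peptides x samples
    sample_class: pd.Series  # per-column: tumor | normal_panel | mtec

    def __post_init__(self) -> None:
        if (self.rphm.values < 0).any():
            raise ValueError("rphm values must be >= 0")
        unknown = set(self.sample_class) - set(SAMPLE_CLASSES)
        if unknown:
            raise ValueError(f"unknown sample classes: {sorted(unknown)}")
        if "tumor" not in set(self.sample_class):
            raise ValueError("cohort needs at least one tumor column")
        if not ({"normal_panel", "mtec"} & set(self.sample_class)):
            raise ValueError("cohort needs at least one baseline column")

    def tumor_columns(self) -> list[str]:
        return list(self.sample_class[self.sample_class == "tumor"].index)

    def baseline_columns(self) -> list[str]:
        mask = self.sample_class.isin(["normal_panel", "mtec"])
        return list(self.sample_class[mask].index)

    @classmethod
    def from_tsv(cls, path) -> "CohortMatrix":
        """Two-row header: sample ids then sample classes."""
        raw = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0)
        classes = pd.Series(
            [c for _, c in raw.columns], index=[s for s, _ in raw.columns]
        )
        raw.columns = classes.index
        return cls(raw.astype(float), classes)

    def to_tsv(self, path) -> None:
        out = self.rphm.copy()
        out.columns = pd.MultiIndex.from_arrays(
            [self.rphm.columns, [self.sample_class[c] for c in self.rphm.columns]]
        )
        out.to_csv(path, sep="\t")


def baseline_value(peptide: str, matrix: CohortMatrix, log_base: float = 10.0) -> float:
    """Back-transformed mean log(rphm+1) over the baseline columns."""
    cols = matrix.baseline_columns()
    if not cols:
        raise ValueError("no baseline columns configured")
    vals = matrix.rphm.loc[peptide, cols].to_numpy(dtype=float)
    mean_log = float(np.mean(np.log(vals + 1.0) / np.log(log_base)))
    return float(log_base**mean_log - 1.0)


def sharing_fraction(
    peptide: str,
    matrix: CohortMatrix,
    min_fold: float = 10.0,
    floor: float = 0.0,
    log_base: float = 10.0,
    log_scale: bool = False,
) -> float:
    """Fraction of tumors expressing >= min_fold above the baseline.

    With a zero baseline (and zero floor) the multiplicative rule is
    replaced by requiring any expression (rphm > 0).  ``log_scale``
    performs the fold comparison on log(rphm+1) instead.
    """
    base = baseline_value(peptide, matrix, log_base)
    tumors = matrix.rphm.loc[peptide, matrix.tumor_columns()].to_numpy(dtype=float)
    threshold_base = max(base, floor)
    if threshold_base == 0:
        hits = tumors > 0
    elif log_scale:
        hits = np.log(tumors + 1.0) >= min_fold * np.log(threshold_base + 1.0)
    else:
        hits = tumors >= min_fold * threshold_base
    return float(np.mean(hits))


def shared_flag(fraction: float, min_frac: float = 0.05) -> bool:
    """Shared when at least ``min_frac`` of tumors pass (inclusive)."""
    return fraction >= min_frac


def sharing_table(matrix: CohortMatrix, min_fold: float = 10.0, min_frac: float = 0.05) -> pd.DataFrame:
    """Baseline, sharing fraction and shared flag for every peptide."""
    rows = []
    for pep in matrix.rphm.index:
        base = baseline_value(pep, matrix)
        frac = sharing_fraction(pep, matrix, min_fold=min_fold)
        rows.append(
            dict(
                peptide=pep,
                baseline_rphm=base,
                sharing_fraction=frac,
                shared=shared_flag(frac, min_frac),
            )
        )
    return pd.DataFrame(rows).set_index("peptide")
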