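"""Packaged study tables.

``validated_antigens`` is the printed relative-quantification table of the
colorectal study's validated tumor antigens (one row per antigen call per
sample: sequence, class, sample, endogenous 127N/126 ratio, mean reporter
intensity, SPS-MS3 127N/126 ratio, synthetic calibration-curve R^2; 'ND'
marks peptides not detected in the SPS-MS3 runs).  ``sample_metadata``
carries the per-sample type (cell line vs primary tissue) and
microsatellite status used by the summary tallies.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

TSA_CLASSES = ("aeTSA", "mTSA")


def _read(name: str) -> pd.DataFrame:
    with resources.files("tsakit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def load_validated_antigens() -> pd.DataFrame:
    df = _read("validated_antigens.tsv")
    for col in ("endogenous_ratio", "mean_intensity", "sps_ms3_ratio", "calibration_r2"):
        df[col] = pd.to_numeric(df[col].replace("ND", np.nan))
    return df


def load_sample_metadata() -> pd.DataFrame:
    return _read("sample_metadata.tsv").set_index("sample_id")


def validated_antigen_tallies(
    antigens: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Headline tallies of the validated-antigen table.

    * ``total_tsas`` — antigen calls labeled aeTSA or mTSA;
    * ``tissue_tsas`` — the subset from primary tissue samples;
    * ``quantified_tsas`` — unique TSA sequences with a numeric SPS-MS3
      ratio (the non-N.D. rows);
    * ``mss_tissue_aetsas`` — aeTSA calls in microsatellite-stable tissues;
    * ``mean_tsas_per_tissue`` — tissue TSA calls per tissue sample.
    """
    df = antigens if antigens is not None else load_validated_antigens()
    meta = metadata if metadata is not None else load_sample_metadata()
    tsa = df[df["antigen_class"].isin(TSA_CLASSES)]
    tissue_ids = set(meta.index[meta["sample_type"] == "tissue"])
    mss_ids = set(meta.index[meta["msi_status"] == "MSS"])
    tissue_tsa = tsa[tsa["sample"].isin(tissue_ids)]
    quantified = tsa[tsa["sps_ms3_ratio"].notna()]["sequence"].nunique()
    mss_aetsa = tsa[
        (tsa["antigen_class"] == "aeTSA")
        & tsa["sample"].isin(tissue_ids & mss_ids)
    ]
    n_tissues = len(tissue_ids)
    return {
        "total_tsas": int(len(tsa)),
        "tissue_tsas": int(len(tissue_tsa)),
        "quantified_tsas": int(quantified),
        "mss_tissue_aetsas": int(len(mss_aetsa)),
        "mean_tsas_per_tissue": len(tissue_tsa) / n_tissues,
    }
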