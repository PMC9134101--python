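"""TMT-based quantitation utilities.

Covers the three mass-spectrometry-side computations of the antigen
validation stage: labeling efficiency (fraction of TMT-labeled PSMs),
SPS-MS3 relative quantification of tumor (127N) versus matched normal
(126) reporter channels with contamination (127C) and intensity-percentile
PSM filters, and the endogenous-versus-synthetic spectral validation by
Pearson correlation of square-root-scaled fragment intensities (a pair is
considered validated at r >= 0.6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

TMT10PLEX_CHANNELS = (
    "126", "127N", "127C", "128N", "128C",
    "129N", "129C", "130N", "130C", "131N",
)


@dataclass
class PsmQuantRecord:
    peptide: str
    sample_id: str
    channel_intensities: dict[str, float]
    is_tmt_labeled: bool = True

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.channel_intensities.values()):
            raise ValueError("channel intensities must be >= 0")

    @property
    def total_intensity(self) -> float:
        return float(sum(self.channel_intensities.values()))


@dataclass
class SpectrumPair:
    peptide: str
    endogenous: list[tuple[str, float, float]]  # (fragment id, m/z, intensity)
    synthetic: list[tuple[str, float, float]]

    @property
    def shared_fragments(self) -> list[str]:
        endo = {f for f, _, _ in self.endogenous}
        synt = {f for f, _, _ in self.synthetic}
        return sorted(endo & synt)


def labeling_efficiency(psms: Sequence[PsmQuantRecord]) -> float:
    """Proportion of TMT-labeled PSMs over all PSMs."""
    if not psms:
        raise ValueError("labeling efficiency undefined for an empty PSM list")
    return sum(p.is_tmt_labeled for p in psms) / len(psms)


@dataclass
class Ms3Result:
    ratio: float | None  # None mirrors a "N.D." table entry
    n_used: int
    n_input: int

    @property
    def quantifiable(self) -> bool:
        return self.ratio is not None


def ms3_ratio(
    psms: Sequence[PsmQuantRecord],
    tumor_channel: str = "127N",
    normal_channel: str = "126",
    empty_channel: str = "127C",
    contamination_tol: float = 0.0,
    intensity_percentile: float = 70.0,
    keep_high: bool = True,
) -> Ms3Result:
    """Tumor/normal reporter ratio from filtered good-quality PSMs.

    PSMs with signal above ``contamination_tol`` in the nominally empty
    channel are excluded; of the remainder, those at or above the
    ``intensity_percentile`` of total intensity are kept (``keep_high=False``
    selects the complementary low-intensity reading).  The ratio is
    mean(tumor) / mean(normal) over surviving PSMs; when nothing survives
    (or the normal channel is silent) the peptide is not quantifiable.
    """
    clean = [
        p
        for p in psms
        if p.channel_intensities.get(empty_channel, 0.0) <= contamination_tol
    ]
    if not clean:
        return Ms3Result(None, 0, len(psms))
    totals = np.array([p.total_intensity for p in clean])
    cut = float(np.percentile(totals, intensity_percentile))
    kept = [
        p
        for p, t in zip(clean, totals)
        if (t >= cut if keep_high else t <= cut)
    ]
    if not kept:
        return Ms3Result(None, 0, len(psms))
    tumor = float(np.mean([p.channel_intensities.get(tumor_channel, 0.0) for p in kept]))
    normal = float(np.mean([p.channel_intensities.get(normal_channel, 0.0) for p in kept]))
    if normal == 0:
        return Ms3Result(None, len(kept), len(psms))
    return Ms3Result(tumor / normal, len(kept), len(psms))


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n_fragments: int

    @property
    def validated(self) -> bool:
        return self.r >= 0.6


def spectral_correlation(pair: SpectrumPair) -> CorrelationResult:
    """Pearson correlation of sqrt intensities over shared fragments.

    Requires at least three shared fragments; scale differences between
    endogenous and synthetic acquisitions cancel out (r is scale
    invariant), so a perfectly scaled pair correlates at 1.
    """
    shared = pair.shared_fragments
    if len(shared) < 3:
        raise ValueError("need >= 3 shared fragments for a correlation")
    endo = {f: i for f, _, i in pair.endogenous}
    synt = {f: i for f, _, i in pair.synthetic}
    x = np.sqrt([endo[f] for f in shared])
    y = np.sqrt([synt[f] for f in shared])
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(shared))
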