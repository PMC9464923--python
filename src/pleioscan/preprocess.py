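"""Pre-FDR quality control: region exclusion and genomic control.

Two regions of extended LD are excluded by default before any cross-trait
FDR work: the MHC (chr6:25,119,106-33,854,733, hg19) and the 8p23.1
inversion region (chr8:7,200,000-12,500,000). Both boundaries are treated
as inclusive.

Genomic control divides every χ² = z² by λGC = median(z²)/median(χ²₁) and
recomputes p from the corrected statistic. λGC is floored at 1 so deflated
statistics are never inflated; the correction is therefore a projection
(applying it twice yields λGC = 1 the second time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._utils import TINY_P
from .exceptions import DegenerateInputError
from .sumstats import HarmonizedPair

logger = logging.getLogger(__name__)

#: median of the χ²₁ distribution
CHI2_1_MEDIAN = float(stats.chi2.median(1))  # 0.4549364...


@dataclass(frozen=True)
class ExclusionRegion:
    """A closed genomic interval [start, end] on one chromosome (1-based, bp)."""

    chrom: int
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    @classmethod
    def parse(cls, text: str, label: str = "") -> "ExclusionRegion":
        """Parse a ``chrom:start-end`` string (commas in numbers allowed)."""
        chrom, span = text.split(":")
        start, end = span.replace(",", "").split("-")
        return cls(int(chrom), int(start), int(end), label)


#: the two regions excluded by default (hg19 coordinates)
DEFAULT_EXCLUSIONS = (
    ExclusionRegion(6, 25_119_106, 33_854_733, "MHC"),
    ExclusionRegion(8, 7_200_000, 12_500_000, "8p23.1"),
)


@dataclass
class GcResult:
    """Genomic-control outcome for one trait."""

    lambda_gc: float          # after flooring at 1
    lambda_raw: float         # median(z²)/median(χ²₁), before flooring
    z_corrected: np.ndarray
    p_corrected: np.ndarray


def exclude_regions(
    pair: HarmonizedPair,
    regions: tuple[ExclusionRegion, ...] = DEFAULT_EXCLUSIONS,
) -> HarmonizedPair:
    """Remove SNPs falling in any exclusion region (boundaries inclusive)."""
    if not regions:
        return pair
    chrom = pair.df["chrom"].to_numpy()
    pos = pair.df["pos"].to_numpy()
    remove = np.zeros(len(pair.df), dtype=bool)
    for region in regions:
        remove |= (chrom == region.chrom) & (pos >= region.start) & (pos <= region.end)
    n_removed = int(remove.sum())
    logger.info("exclude_regions: removed %d of %d SNPs", n_removed, len(pair.df))
    if n_removed == len(pair.df):
        logger.warning("exclude_regions: all SNPs removed")
    out = HarmonizedPair(
        pair.df.loc[~remove].reset_index(drop=True),
        pair.trait_a,
        pair.trait_b,
        dict(pair.n_dropped),
    )
    out.n_dropped["region_excluded"] = n_removed
    return out


def genomic_control(pair: HarmonizedPair, trait: str) -> GcResult:
    """Compute λGC for one trait and the corrected z and p vectors.

    λGC = median(z²)/median(χ²₁), floored at 1. Corrected χ² = z²/λGC; the
    corrected p is the χ²₁ survival function of the corrected statistic and
    the corrected z is z/√λGC (so z and p stay mutually consistent). The
    rank order of p-values is preserved.
    """
    z = pair.z(trait)
    if len(z) < 100:
        logger.warning("genomic_control: only %d SNPs; λGC estimate will be noisy", len(z))
    if np.all(z == 0):
        raise DegenerateInputError("genomic_control: all z-scores are zero")
    lambda_raw = float(np.median(z**2) / CHI2_1_MEDIAN)
    lam = max(1.0, lambda_raw)
    z_corr = z / np.sqrt(lam)
    p_corr = np.clip(stats.chi2.sf(z_corr**2, df=1), TINY_P, 1.0)
    logger.info("genomic_control[%s]: λGC = %.4f (raw %.4f)", trait, lam, lambda_raw)
    return GcResult(lambda_gc=lam, lambda_raw=lambda_raw, z_corrected=z_corr, p_corrected=p_corr)


def apply_genomic_control(pair: HarmonizedPair) -> tuple[HarmonizedPair, GcResult, GcResult]:
    """Apply genomic control to both traits independently; returns the corrected pair."""
    gc_a = genomic_control(pair, "a")
    gc_b = genomic_control(pair, "b")
    corrected = pair.replace(
        z_a=gc_a.z_corrected, p_a=gc_a.p_corrected, z_b=gc_b.z_corrected, p_b=gc_b.p_corrected
    )
    return corrected, gc_a, gc_b
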