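"""Approximate-Bayes-factor colocalization of a trait signal with a QTL signal.

For each SNP the Wakefield approximate Bayes factor against the null is

    log ABF = 0.5 · (log(1 − r) + r·z²),   r = w / (v + w)

with v the variance of the effect estimate (SE², or 2/n on the
standardized-trait scale when only z and n are available) and w the prior
effect variance. Under the single-causal-variant assumption, the evidence
for the five hypotheses about a region is

    H0: no causal SNP            1
    H1: trait only               p1  · Σᵢ ABF_trait(i)
    H2: QTL only                 p2  · Σⱼ ABF_qtl(j)
    H3: distinct causal SNPs     p1·p2 · Σ_{i≠j} ABF_trait(i)·ABF_qtl(j)
    H4: one shared causal SNP    p12 · Σᵢ ABF_trait(i)·ABF_qtl(i)

normalized to posterior probabilities PP0..PP4 (all sums in log space).
A posterior ≥ 0.80 is flagged as supporting that hypothesis; the
sensitivity analysis repeats the computation under a halved p12 and reports
whether the supported hypothesis is unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .exceptions import AlignmentError, ConfigurationError
from .sumstats import SummaryStats

logger = logging.getLogger(__name__)

DECISION_PP = 0.80
#: default prior effect SDs: case-control trait (log-odds scale) and
#: quantitative molecular trait
W_TRAIT_DEFAULT = 0.15**2
W_QTL_DEFAULT = 0.20**2
HALF_WINDOW = 250_000
SENSITIVITY_P12 = (1e-5, 5e-6)


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP priors: trait-only (p1), QTL-only (p2), shared (p12)."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self):
        for name, v in (("p1", self.p1), ("p2", self.p2), ("p12", self.p12)):
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"prior {name} must be in (0, 1), got {v}")
        if self.p12 > min(self.p1, self.p2):
            logger.warning("p12 = %g exceeds min(p1, p2); unusual prior choice", self.p12)


DEFAULT_PRIORS = ColocPriors()


def log_abf(z: np.ndarray, v: np.ndarray, w: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor against the null, per SNP."""
    z = np.asarray(z, float)
    v = np.asarray(v, float)
    if np.any(v <= 0) or w <= 0:
        raise ConfigurationError("v and w must be positive")
    r = w / (v + w)
    return 0.5 * (np.log1p(-r) + r * z * z)


@dataclass
class RegionData:
    """Aligned per-SNP statistics for a trait and a molecular QTL in one region."""

    df: pd.DataFrame  # snp, z_trait, v_trait, z_qtl, v_qtl

    def __post_init__(self):
        if len(self.df) < 2:
            raise ConfigurationError("a coloc region needs at least 2 SNPs")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_arrays(cls, snp, z_trait, v_trait, z_qtl, v_qtl) -> "RegionData":
        n = {len(np.atleast_1d(a)) for a in (snp, z_trait, z_qtl)}
        if len(n) != 1:
            raise AlignmentError("trait and QTL SNP vectors differ in length")
        return cls(pd.DataFrame({
            "snp": snp,
            "z_trait": np.asarray(z_trait, float),
            "v_trait": np.broadcast_to(np.asarray(v_trait, float), (len(snp),)).copy(),
            "z_qtl": np.asarray(z_qtl, float),
            "v_qtl": np.broadcast_to(np.asarray(v_qtl, float), (len(snp),)).copy(),
        }))

    @classmethod
    def extract(
        cls,
        trait: SummaryStats,
        qtl: SummaryStats,
        chrom: int,
        center: int,
        half_window: int = HALF_WINDOW,
    ) -> "RegionData":
        """Intersect the two tables within ``center ± half_window`` on ``chrom``.

        Effect-estimate variances are approximated as 2/n from z and n
        (standardized-trait convention); supply SE² columns via
        :meth:`from_arrays` when true standard errors are available.
        """
        win = (trait.df["chrom"] == chrom) & (trait.df["pos"] - center).abs().le(half_window)
        t = trait.df.loc[win]
        merged = t.merge(qtl.df, on="snp", suffixes=("_t", "_q"))
        if len(merged) < 2:
            raise AlignmentError(
                f"fewer than 2 shared SNPs in {chrom}:{center}±{half_window}")
        logger.info("coloc region %d:%d±%d: %d shared SNPs (approximating v as 2/n)",
                    chrom, center, half_window, len(merged))
        return cls(pd.DataFrame({
            "snp": merged["snp"],
            "z_trait": merged["z_t"],
            "v_trait": 2.0 / merged["n_t"],
            "z_qtl": merged["z_q"],
            "v_qtl": 2.0 / merged["n_q"],
        }))


HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


@dataclass
class ColocResult:
    """Posterior probabilities of H0-H4 for one region."""

    pp: np.ndarray                     # length 5, sums to 1
    lbf_trait: np.ndarray = field(repr=False, default=None)
    lbf_qtl: np.ndarray = field(repr=False, default=None)
    priors: ColocPriors = DEFAULT_PRIORS
    n_snps: int = 0

    @property
    def decision(self) -> str | None:
        """The hypothesis with posterior ≥ 0.80, if any."""
        i = int(np.argmax(self.pp))
        return HYPOTHESES[i] if self.pp[i] >= DECISION_PP else None

    def __getitem__(self, name: str) -> float:
        return float(self.pp[HYPOTHESES.index(name)])

    def summary(self) -> str:
        parts = [f"PP{i}={v:.4f}" for i, v in enumerate(self.pp)]
        return f"coloc ({self.n_snps} SNPs): " + " ".join(parts) + \
            (f"  -> {self.decision}" if self.decision else "")


def colocalize(
    region: RegionData,
    priors: ColocPriors = DEFAULT_PRIORS,
    w_trait: float = W_TRAIT_DEFAULT,
    w_qtl: float = W_QTL_DEFAULT,
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""
    df = region.df
    l1 = log_abf(df["z_trait"].to_numpy(), df["v_trait"].to_numpy(), w_trait)
    l2 = log_abf(df["z_qtl"].to_numpy(), df["v_qtl"].to_numpy(), w_qtl)

    sum1 = logsumexp(l1)
    sum2 = logsumexp(l2)
    sum12 = logsumexp(l1 + l2)
    lh0 = 0.0
    lh1 = np.log(priors.p1) + sum1
    lh2 = np.log(priors.p2) + sum2
    # Σ_{i≠j} e^{l1_i + l2_j} = (Σ e^{l1})(Σ e^{l2}) − Σ e^{l1+l2}, in log space
    cross = sum1 + sum2
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = -np.expm1(np.clip(sum12 - cross, None, 0.0))
        lh3_sum = cross + np.log(diff) if diff > 0 else -np.inf
    lh3 = np.log(priors.p1) + np.log(priors.p2) + lh3_sum
    lh4 = np.log(priors.p12) + sum12

    lh = np.array([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(lh - logsumexp(lh))
    return ColocResult(pp=pp, lbf_trait=l1, lbf_qtl=l2, priors=priors, n_snps=len(df))


@dataclass
class SensitivityResult:
    """Coloc results under a grid of p12 priors with a stability flag."""

    results: dict[float, ColocResult]
    stable: bool

    def summary(self) -> str:
        lines = [f"p12={p12:g}: {res.summary()}" for p12, res in self.results.items()]
        lines.append(f"stable decision: {self.stable}")
        return "\n".join(lines)


def sensitivity(
    region: RegionData,
    p12_values: tuple[float, ...] = SENSITIVITY_P12,
    priors: ColocPriors = DEFAULT_PRIORS,
    w_trait: float = W_TRAIT_DEFAULT,
    w_qtl: float = W_QTL_DEFAULT,
) -> SensitivityResult:
    """Repeat colocalization under each p12; stable when every run that
    reaches the 0.80 support level supports the same hypothesis."""
    results = {
        p12: colocalize(region, ColocPriors(priors.p1, priors.p2, p12), w_trait, w_qtl)
        for p12 in p12_values
    }
    decisions = {res.decision for res in results.values()}
    stable = len(decisions) == 1
    return SensitivityResult(results=results, stable=stable)
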