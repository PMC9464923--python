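"""Stratified conditional Q-Q curves with random LD pruning.

A conditional Q-Q curve compares the distribution of one trait's p-values
inside strata defined by the other trait's significance (p < 1, 0.1, 0.01,
0.001 by default). Spurious enrichment from LD is mitigated by random
pruning: in each iteration one SNP is drawn uniformly from every LD block
and the empirical CDF is computed on that subset; exceedance fractions are
averaged over iterations on a fixed grid of nominal -log10 p points.

Plotting follows the conventional orientation: nominal -log10 p on the
vertical axis against the empirical -log10 quantile on the horizontal axis,
so pleiotropic enrichment appears as a leftward deflection of the tighter
strata away from the identity line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import derive_seed, neglog10
from .exceptions import ConfigurationError
from .ld import LdReference
from .sumstats import HarmonizedPair

logger = logging.getLogger(__name__)

DEFAULT_STRATA = (1.0, 0.1, 0.01, 0.001)
#: curves are truncated at nominal -log10 p = 7.3 (p = 5e-8)
NEGLOG_CAP = 7.3
GRID_STEP = 0.01


class _Pruner:
    """Uniform one-SNP-per-block sampler over the SNPs of a harmonized pair."""

    def __init__(self, pair: HarmonizedPair, ld: LdReference):
        snps = pair.df["snp"].to_numpy()
        labels = ld.block_labels(snps.tolist())
        _, inverse = np.unique(labels, return_inverse=True)
        # members ordered by snp id within each block: draws then depend only
        # on the SNP *set*, making curves invariant to input row order
        order = np.lexsort((snps, inverse))
        self.sorted_idx = order
        sorted_labels = inverse[order]
        boundaries = np.flatnonzero(np.diff(sorted_labels)) + 1
        self.starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(sorted_labels)]])
        self.sizes = ends - self.starts

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        """Indices (into the pair's rows) of one uniformly chosen SNP per block."""
        offsets = rng.integers(0, self.sizes)
        return self.sorted_idx[self.starts + offsets]


def random_prune(
    pair: HarmonizedPair,
    ld: LdReference,
    iterations: int = 100,
    seed: int = 0,
) -> list[np.ndarray]:
    """Random pruning subsets: each contains exactly one SNP id per LD block."""
    if iterations < 1:
        raise ConfigurationError("iterations must be >= 1")
    pruner = _Pruner(pair, ld)
    rng = np.random.default_rng(seed)
    snps = pair.df["snp"].to_numpy()
    return [np.sort(snps[pruner.draw(rng)]) for _ in range(iterations)]


@dataclass
class StratumCurve:
    """Averaged Q-Q curve for one conditioning stratum."""

    threshold: float
    nominal: np.ndarray      # grid of nominal -log10 p values (x < 7.3)
    exceedance: np.ndarray   # averaged fraction of stratum with -log10 p >= nominal
    mean_count: float        # stratum size averaged over iterations

    @property
    def empirical(self) -> np.ndarray:
        """-log10 of the averaged empirical CDF exceedance (inf where empty)."""
        with np.errstate(divide="ignore"):
            return -np.log10(self.exceedance)

    def nominal_at(self, empirical_x: float) -> float:
        """Nominal -log10 p at a given empirical coordinate (curve inversion).

        Under the null this equals ``empirical_x``; enrichment pushes it up.
        """
        emp = self.empirical
        ok = np.isfinite(emp)
        return float(np.interp(empirical_x, emp[ok], self.nominal[ok]))


@dataclass
class QQStrata:
    """Conditional Q-Q curves for all strata of one primary trait."""

    primary: str
    strata: dict[float, StratumCurve]
    iterations: int

    def curve(self, threshold: float) -> StratumCurve:
        return self.strata[threshold]

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for t, c in self.strata.items():
            frames.append(
                pd.DataFrame(
                    {"threshold": t, "nominal": c.nominal, "exceedance": c.exceedance,
                     "empirical": c.empirical, "mean_count": c.mean_count}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def plot(self, ax=None, max_axis: float = NEGLOG_CAP):
        """Nominal -log10 p (y) vs empirical -log10 quantile (x), one line per stratum."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        for t, c in sorted(self.strata.items(), reverse=True):
            ok = np.isfinite(c.empirical)
            ax.plot(c.empirical[ok], c.nominal[ok], label=f"p < {t:g}")
        ax.plot([0, max_axis], [0, max_axis], "k:", lw=1, label="null")
        ax.set_xlim(0, max_axis)
        ax.set_ylim(0, max_axis)
        ax.set_xlabel(r"empirical $-\log_{10}(q)$")
        ax.set_ylabel(r"nominal $-\log_{10}(p)$")
        ax.legend(frameon=False, fontsize=8)
        return ax


def conditional_qq(
    pair: HarmonizedPair,
    ld: LdReference,
    primary: str = "a",
    strata: tuple[float, ...] = DEFAULT_STRATA,
    iterations: int = 100,
    seed: int = 0,
) -> QQStrata:
    """Stratified conditional Q-Q curves averaged over random pruning iterations.

    For each iteration and conditioning threshold t, the exceedance fraction
    of primary-trait p among pruned SNPs whose conditioning-trait p < t is
    evaluated on the fixed nominal grid 0..7.3 (step 0.01); fractions are
    averaged across iterations. A stratum empty in any iteration is dropped
    with a warning.
    """
    strata = tuple(strata)
    if any(not (0.0 < t <= 1.0) for t in strata):
        raise ConfigurationError(f"strata thresholds must be in (0, 1]: {strata}")
    if list(strata) != sorted(strata, reverse=True):
        raise ConfigurationError("strata must be in descending order")
    key = "a" if primary in ("a", pair.trait_a) else "b"
    other = "b" if key == "a" else "a"
    x1 = neglog10(pair.df[f"p_{key}"].to_numpy())
    p2 = pair.df[f"p_{other}"].to_numpy()

    grid = np.round(np.arange(0.0, NEGLOG_CAP, GRID_STEP), 10)
    edges = np.concatenate([grid, [np.inf]])
    pruner = _Pruner(pair, ld)
    rng = np.random.default_rng(derive_seed(seed, f"qq-{key}"))

    sums = {t: np.zeros(len(grid)) for t in strata}
    counts = {t: 0.0 for t in strata}
    dead: set[float] = set()
    for _ in range(iterations):
        idx = pruner.draw(rng)
        for t in strata:
            sel = idx[p2[idx] < t]
            if len(sel) == 0:
                dead.add(t)
                continue
            hist, _ = np.histogram(x1[sel], bins=edges)
            exceed = np.cumsum(hist[::-1])[::-1] / len(sel)
            sums[t] += exceed
            counts[t] += len(sel)

    out: dict[float, StratumCurve] = {}
    for t in strata:
        if t in dead:
            logger.warning("conditional_qq: stratum p < %g empty in >= 1 iteration; dropped", t)
            continue
        out[t] = StratumCurve(
            threshold=t,
            nominal=grid,
            exceedance=sums[t] / iterations,
            mean_count=counts[t] / iterations,
        )
    return QQStrata(primary=key, strata=out, iterations=iterations)
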