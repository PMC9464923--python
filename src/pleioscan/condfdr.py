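"""Conditional and conjunctional FDR estimation.

The conditional FDR of a SNP for a primary trait given a conditioning trait
is the (conservative, π0 = 1) posterior probability of being null given that
both observed p-values are at most the observed ones:

    condFDR(p1 | p2 <= t) = min(1, p1 / F_hat(p1 | p2 <= t))

where F_hat is the empirical CDF of primary p among randomly pruned SNPs in
the cumulative conditioning stratum. The estimate is tabulated on a 2-D grid
over (-log10 p_primary) x (-log10 p_conditioning threshold), averaged over
pruning iterations, monotonized along the primary axis, and then assigned to
*every* SNP (pruned or not) by bilinear interpolation — the lookup-table
architecture of the conditional-FDR software family.

The conjunctional FDR, which upper-bounds the posterior probability that a
SNP is null for either trait, is the maximum of the two reciprocal
conditional FDRs; the max rule holds exactly for every SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import TINY_P, derive_seed, neglog10
from .exceptions import ConfigurationError
from .ld import LdReference
from .qq import _Pruner
from .sumstats import HarmonizedPair

logger = logging.getLogger(__name__)

GRID_MAX = 10.0
GRID_STEP = 0.1
SIG_THRESHOLD = 0.05


def default_edges() -> np.ndarray:
    return np.round(np.arange(0.0, GRID_MAX + GRID_STEP / 2, GRID_STEP), 10)


@dataclass
class FdrGrid:
    """2-D conditional-FDR lookup over (-log10 p_primary) x (-log10 p_cond threshold).

    ``values[i, j]`` is the estimated condFDR at primary p = 10**-edges[i]
    inside the cumulative stratum conditioning p <= 10**-cond_edges[j].
    """

    primary_edges: np.ndarray
    cond_edges: np.ndarray
    values: np.ndarray
    iterations: int
    primary: str = "a"

    def lookup(self, x_primary: np.ndarray, x_cond: np.ndarray) -> np.ndarray:
        """Bilinear interpolation, clamping out-of-range coordinates to the grid."""
        xp = np.clip(np.asarray(x_primary, float), self.primary_edges[0], self.primary_edges[-1])
        xc = np.clip(np.asarray(x_cond, float), self.cond_edges[0], self.cond_edges[-1])
        i = np.clip(np.searchsorted(self.primary_edges, xp, side="right") - 1, 0,
                    len(self.primary_edges) - 2)
        j = np.clip(np.searchsorted(self.cond_edges, xc, side="right") - 1, 0,
                    len(self.cond_edges) - 2)
        x0 = self.primary_edges[i]
        x1 = self.primary_edges[i + 1]
        y0 = self.cond_edges[j]
        y1 = self.cond_edges[j + 1]
        tx = np.where(x1 > x0, (xp - x0) / (x1 - x0), 0.0)
        ty = np.where(y1 > y0, (xc - y0) / (y1 - y0), 0.0)
        v = self.values
        interp = (
            v[i, j] * (1 - tx) * (1 - ty)
            + v[i + 1, j] * tx * (1 - ty)
            + v[i, j + 1] * (1 - tx) * ty
            + v[i + 1, j + 1] * tx * ty
        )
        return np.clip(interp, TINY_P, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.primary_edges, name="neglog_p_primary"),
            columns=pd.Index(self.cond_edges, name="neglog_p_cond"),
        )


def conditional_fdr_curve(
    p_primary: np.ndarray,
    in_stratum: np.ndarray,
    eval_p: np.ndarray,
) -> np.ndarray:
    """condFDR at the given primary p levels for one explicit stratum.

    Direct (non-gridded) evaluation used for small worked examples and as a
    reference path: condFDR = min(1, p / F_hat(p)) with F_hat the stratum
    ECDF (<= convention) floored at one observation.
    """
    ps = np.sort(np.asarray(p_primary, float)[np.asarray(in_stratum, bool)])
    n = len(ps)
    if n == 0:
        return np.ones_like(np.asarray(eval_p, float))
    counts = np.searchsorted(ps, np.asarray(eval_p, float), side="right")
    return np.minimum(1.0, np.asarray(eval_p, float) * n / np.maximum(counts, 1))


#: conditioning strata with fewer members than this are treated as undefined:
#: an ECDF on a handful of SNPs is dominated by the SNP's own rank-1 term
#: (its smallest attainable condFDR is p·n_stratum), which is badly
#: anti-conservative in the deep joint tail
MIN_STRATUM_SIZE = 10


def build_fdr_grid(
    pair: HarmonizedPair,
    ld: LdReference,
    primary: str = "a",
    iterations: int = 100,
    seed: int = 0,
    edges: np.ndarray | None = None,
    min_stratum_size: int = MIN_STRATUM_SIZE,
) -> FdrGrid:
    """Tabulate condFDR(primary | conditioning) averaged over pruning iterations.

    Per iteration the 2-D exceedance counts #(x1 >= e_i, x2 >= e_j) are taken
    over one random SNP per LD block; cells of an empty or under-populated
    stratum (< ``min_stratum_size`` members) are excluded from the average,
    and conditioning columns undefined in *all* iterations inherit the
    nearest looser column. Finally the grid is monotonized along the primary
    axis (running maximum from smallest to largest p).
    """
    if iterations < 1:
        raise ConfigurationError("iterations must be >= 1")
    edges = default_edges() if edges is None else np.asarray(edges, float)
    key = "a" if primary in ("a", pair.trait_a) else "b"
    other = "b" if key == "a" else "a"
    x1 = neglog10(pair.df[f"p_{key}"].to_numpy())
    x2 = neglog10(pair.df[f"p_{other}"].to_numpy())

    bins = np.concatenate([edges, [np.inf]])
    p_levels = 10.0 ** (-edges)
    pruner = _Pruner(pair, ld)
    rng = np.random.default_rng(derive_seed(seed, f"condfdr-{key}"))

    g = len(edges)
    acc = np.zeros((g, g))
    n_def = np.zeros((g, g))
    row_idx = np.arange(g)[:, None]
    for _ in range(iterations):
        idx = pruner.draw(rng)
        hist, _, _ = np.histogram2d(x1[idx], x2[idx], bins=[bins, bins])
        # suffix-cumulate both axes: counts[i, j] = #(x1 >= e_i and x2 >= e_j)
        counts = np.cumsum(np.cumsum(hist[::-1, ::-1], axis=0), axis=1)[::-1, ::-1]
        n_strat = counts[0, :]                      # stratum sizes per threshold
        with np.errstate(divide="ignore", invalid="ignore"):
            cells = np.minimum(
                1.0, p_levels[:, None] * n_strat[None, :] / counts
            )
        # below the smallest observed p in a stratum the ECDF is zero and the
        # ratio carries no information; extrapolate the deepest observed cell
        # value as a constant (counts are a suffix of zeros along the p axis)
        observed = counts >= 1
        last = np.maximum.accumulate(np.where(observed, row_idx, 0), axis=0)
        cells = cells[last, np.arange(g)[None, :]]
        defined = n_strat >= max(min_stratum_size, 1)
        defined[0] = n_strat[0] > 0  # the all-SNPs column is always usable
        acc[:, defined] += cells[:, defined]
        n_def[:, defined] += 1.0

    values = np.full((g, g), np.nan)
    np.divide(acc, n_def, out=values, where=n_def > 0)
    # columns never adequately populated inherit the nearest looser threshold
    for j in range(1, g):
        if np.isnan(values[0, j]):
            values[:, j] = values[:, j - 1]
    if np.isnan(values).any():
        raise ConfigurationError("condFDR grid empty: no pruned SNPs at the loosest threshold")
    # monotonize: condFDR non-decreasing with increasing primary p
    values = np.maximum.accumulate(values[::-1, :], axis=0)[::-1, :]
    values = np.clip(values, TINY_P, 1.0)
    return FdrGrid(primary_edges=edges, cond_edges=edges.copy(), values=values,
                   iterations=iterations, primary=key)


@dataclass
class FdrAssignment:
    """Per-SNP condFDR/conjFDR values with significance flags at 0.05.

    ``df`` columns: snp, chrom, pos, z_a, z_b, p_a, p_b, condfdr_ab (trait a
    given b), condfdr_ba, conjfdr, sig_condfdr_ab, sig_condfdr_ba, sig_conjfdr.
    conjfdr = max(condfdr_ab, condfdr_ba) exactly for every SNP.
    """

    df: pd.DataFrame
    threshold: float = SIG_THRESHOLD

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_values(
        cls,
        df: pd.DataFrame,
        threshold: float = SIG_THRESHOLD,
    ) -> "FdrAssignment":
        """Construct directly from a table that already carries FDR columns.

        Requires snp/chrom/pos/z_a/z_b/p_a/p_b plus condfdr_ab and conjfdr;
        condfdr_ba defaults to conjfdr (consistent with the max rule whenever
        conjfdr >= condfdr_ab).
        """
        df = df.copy()
        if "condfdr_ba" not in df.columns:
            df["condfdr_ba"] = df["conjfdr"]
        if (df["conjfdr"] + 1e-12 < np.maximum(df["condfdr_ab"], df["condfdr_ba"])).any():
            raise ConfigurationError("conjfdr must be >= both condFDR columns")
        for flag, col in (("sig_condfdr_ab", "condfdr_ab"), ("sig_condfdr_ba", "condfdr_ba"),
                          ("sig_conjfdr", "conjfdr")):
            df[flag] = df[col] < threshold
        return cls(df=df, threshold=threshold)

    def write(self, path) -> None:
        out = self.df.rename(
            columns={"snp": "SNP", "chrom": "CHR", "pos": "BP", "p_a": "P_A", "p_b": "P_B",
                     "z_a": "Z_A", "z_b": "Z_B", "condfdr_ab": "CONDFDR_AB",
                     "condfdr_ba": "CONDFDR_BA", "conjfdr": "CONJFDR"}
        )
        cols = ["SNP", "CHR", "BP", "P_A", "P_B", "Z_A", "Z_B",
                "CONDFDR_AB", "CONDFDR_BA", "CONJFDR"]
        out[cols].to_csv(path, sep="\t", index=False)


def assign_fdr(
    pair: HarmonizedPair,
    grid_ab: FdrGrid,
    grid_ba: FdrGrid,
    threshold: float = SIG_THRESHOLD,
) -> FdrAssignment:
    """Assign condFDR (both directions) and conjFDR to every SNP in the pair."""
    x_a = neglog10(pair.df["p_a"].to_numpy())
    x_b = neglog10(pair.df["p_b"].to_numpy())
    if (x_a > grid_ab.primary_edges[-1]).any() or (x_b > grid_ba.primary_edges[-1]).any():
        logger.warning("assign_fdr: some SNPs fall outside the grid; clamped to boundary")
    condfdr_ab = grid_ab.lookup(x_a, x_b)
    condfdr_ba = grid_ba.lookup(x_b, x_a)
    df = pair.df[["snp", "chrom", "pos", "z_a", "z_b", "p_a", "p_b"]].copy()
    df["condfdr_ab"] = condfdr_ab
    df["condfdr_ba"] = condfdr_ba
    df["conjfdr"] = np.maximum(condfdr_ab, condfdr_ba)
    for flag, col in (("sig_condfdr_ab", "condfdr_ab"), ("sig_condfdr_ba", "condfdr_ba"),
                      ("sig_conjfdr", "conjfdr")):
        df[flag] = df[col] < threshold
    return FdrAssignment(df=df, threshold=threshold)


class CondFdr:
    """Model object bundling the full conditional-FDR computation for one pair.

    Mirrors the fit/results idiom: construct from data, call :meth:`fit`,
    read estimates off the returned :class:`CondFdrResults`.
    """

    def __init__(self, pair: HarmonizedPair, ld: LdReference):
        self.pair = pair
        self.ld = ld

    def fit(self, iterations: int = 100, seed: int = 0,
            threshold: float = SIG_THRESHOLD) -> "CondFdrResults":
        grid_ab = build_fdr_grid(self.pair, self.ld, "a", iterations, seed)
        grid_ba = build_fdr_grid(self.pair, self.ld, "b", iterations, seed)
        assignment = assign_fdr(self.pair, grid_ab, grid_ba, threshold)
        return CondFdrResults(model=self, grid_ab=grid_ab, grid_ba=grid_ba,
                              assignment=assignment)


@dataclass
class CondFdrResults:
    model: CondFdr = field(repr=False)
    grid_ab: FdrGrid
    grid_ba: FdrGrid
    assignment: FdrAssignment

    def summary(self) -> str:
        df = self.assignment.df
        t = self.assignment.threshold
        pair = self.model.pair
        lines = [
            "Conditional/conjunctional FDR results",
            "=" * 44,
            f"traits:            {pair.trait_a} | {pair.trait_b}",
            f"SNPs:              {len(df)}",
            f"pruning iterations:{self.grid_ab.iterations}",
            f"condFDR({pair.trait_a}|{pair.trait_b}) < {t}: {int(df['sig_condfdr_ab'].sum())}",
            f"condFDR({pair.trait_b}|{pair.trait_a}) < {t}: {int(df['sig_condfdr_ba'].sum())}",
            f"conjFDR < {t}:      {int(df['sig_conjfdr'].sum())}",
        ]
        return "\n".join(lines)

    def plot_manhattan(self, statistic: str = "conjfdr", ax=None):
        """Manhattan-style plot ranking SNPs by -log10 of the FDR statistic."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        df = self.assignment.df.sort_values(["chrom", "pos"])
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        offset = 0.0
        ticks = []
        for chrom, grp in df.groupby("chrom", sort=True):
            x = offset + (grp["pos"] - grp["pos"].min()).to_numpy()
            ax.scatter(x, -np.log10(grp[statistic]), s=2,
                       color="C0" if chrom % 2 else "C1", rasterized=True)
            ticks.append((offset + x[-1]) / 2 if len(x) else offset)
            offset = x[-1] + 1e6 if len(x) else offset
        ax.axhline(-np.log10(self.assignment.threshold), color="red", lw=0.8, ls="--")
        ax.set_ylabel(rf"$-\log_{{10}}$({statistic})")
        ax.set_xlabel("chromosome")
        return ax
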