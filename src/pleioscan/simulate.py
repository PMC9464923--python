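"""Two-trait GWAS summary-statistic generator with known causal truth.

Each SNP belongs to a disjoint equicorrelated LD block. Per block, a causal
component is drawn from the four-component mixture

    null : trait-1-specific : trait-2-specific : shared
    1-π1s-π2s-π12 :   π1s    :     π2s         :  π12

and effect sizes for the block's *anchor* SNP are drawn on the
standardized-genotype scale: β1 ~ N(0, σβ1²), β2 ~ N(0, σβ2²), correlated
with ρ12 inside the shared component and independent otherwise. Tag SNPs in
the block inherit the component label and carry β_tag = √r2_within · β_anchor
(a tag of a causal block genuinely tags association signal). Observed
z-scores are

    z_t = √n_t · β + ε_t,   ε_t block-equicorrelated, Var = σ0t², corr = r2_within

so null SNPs in one block are correlated, which stresses the pruning
machinery downstream. σ0t > 1 models uniform inflation. p = 2·Φ(−|z|).
No allele frequencies, genotypes or population structure are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import z_to_p
from .exceptions import ConfigurationError
from .ld import LdReference
from .sumstats import SummaryStats

COMPONENTS = np.array(["null", "c1", "c2", "both"])

# non-strand-ambiguous allele pairs the generator assigns
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic two-trait GWAS.

    Defaults give two symmetric moderately polygenic traits with a shared
    component of the same size as the specific ones (π = 0.005 each),
    per-causal-SNP signal n·σβ² = 40, mostly-concordant shared effects
    (ρ12 = 0.8), no uniform inflation, and five-SNP LD blocks at r² = 0.7.
    """

    m: int = 100_000
    block_size: int | tuple[int, int] = 5      # fixed size, or (lo, hi) inclusive uniform
    r2_within: float = 0.7
    pi1s: float = 0.005
    pi2s: float = 0.005
    pi12: float = 0.005
    sigma_b1_sq: float = 4.0e-4
    sigma_b2_sq: float = 4.0e-4
    rho12: float = 0.8
    n1: int = 100_000
    n2: int = 100_000
    sigma01: float = 1.0
    sigma02: float = 1.0
    seed: int = 0

    def __post_init__(self):
        pis = (self.pi1s, self.pi2s, self.pi12)
        if any(p < 0 for p in pis) or sum(pis) > 1:
            raise ConfigurationError(f"component probabilities invalid: {pis}")
        if self.sigma_b1_sq < 0 or self.sigma_b2_sq < 0:
            raise ConfigurationError("discoverabilities must be >= 0")
        if not -1.0 <= self.rho12 <= 1.0:
            raise ConfigurationError(f"rho12 must be in [-1, 1], got {self.rho12}")
        if not 0.0 <= self.r2_within <= 1.0:
            raise ConfigurationError(f"r2_within must be in [0, 1], got {self.r2_within}")
        if self.sigma01 <= 0 or self.sigma02 <= 0:
            raise ConfigurationError("null-score SDs must be positive")
        if self.m < 1 or self.n1 < 1 or self.n2 < 1:
            raise ConfigurationError("m, n1, n2 must be positive")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class SimulationResult:
    stats1: SummaryStats
    stats2: SummaryStats
    ld: LdReference
    truth: pd.DataFrame   # snp, component, beta1, beta2, block
    config: SimulationConfig = field(repr=False, default=None)

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.stats1.write(outdir / "trait1.sumstats.tsv")
        self.stats2.write(outdir / "trait2.sumstats.tsv")
        self.ld.to_block_file(outdir / "ld_blocks.tsv")
        out = self.truth.rename(
            columns={"snp": "SNP", "component": "COMPONENT", "beta1": "BETA1",
                     "beta2": "BETA2", "block": "BLOCK"}
        )
        out.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _block_sizes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(config.block_size, int):
        if config.block_size < 1:
            raise ConfigurationError("block_size must be >= 1")
        n_full = config.m // config.block_size
        sizes = np.full(n_full, config.block_size, dtype=np.int64)
        rem = config.m - n_full * config.block_size
        if rem:
            sizes = np.append(sizes, rem)
        return sizes
    lo, hi = config.block_size
    if lo < 1 or hi < lo:
        raise ConfigurationError(f"invalid block_size range {config.block_size}")
    sizes = []
    total = 0
    while total < config.m:
        s = int(rng.integers(lo, hi + 1))
        s = min(s, config.m - total)
        sizes.append(s)
        total += s
    return np.array(sizes, dtype=np.int64)


def simulate(config: SimulationConfig) -> SimulationResult:
    """Draw one synthetic dataset; bit-identical for identical config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    sizes = _block_sizes(config, rng)
    n_blocks = len(sizes)
    block = np.repeat(np.arange(n_blocks), sizes)
    m = config.m
    root_r2 = np.sqrt(config.r2_within)

    # per-block component and anchor effects
    p0 = 1.0 - config.pi1s - config.pi2s - config.pi12
    comp_block = rng.choice(4, size=n_blocks, p=[p0, config.pi1s, config.pi2s, config.pi12])
    s1 = np.sqrt(config.sigma_b1_sq)
    s2 = np.sqrt(config.sigma_b2_sq)
    x = rng.standard_normal(n_blocks)
    y = rng.standard_normal(n_blocks)
    b1_anchor = np.where(np.isin(comp_block, (1, 3)), s1 * x, 0.0)
    rho = config.rho12
    b2_shared = s2 * (rho * x + np.sqrt(max(0.0, 1.0 - rho**2)) * y)
    b2_anchor = np.where(comp_block == 2, s2 * y, np.where(comp_block == 3, b2_shared, 0.0))

    # anchor position within each block; tags scaled by sqrt(r2)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    anchor_offset = rng.integers(0, sizes)
    anchor_idx = starts + anchor_offset
    scale = np.full(m, root_r2)
    scale[anchor_idx] = 1.0
    beta1 = b1_anchor[block] * scale
    beta2 = b2_anchor[block] * scale

    # block-equicorrelated noise, independent across traits
    def noise(sigma0: float) -> np.ndarray:
        shared = rng.standard_normal(n_blocks)[block]
        own = rng.standard_normal(m)
        r2 = config.r2_within
        return sigma0 * (np.sqrt(r2) * shared + np.sqrt(1.0 - r2) * own)

    z1 = np.sqrt(config.n1) * beta1 + noise(config.sigma01)
    z2 = np.sqrt(config.n2) * beta2 + noise(config.sigma02)

    width = len(str(m))
    snp = np.array([f"snp{i:0{width}d}" for i in range(m)])
    # lay blocks out across chromosomes 1-22: 10 kb spacing within a block,
    # 1 Mb between blocks so distinct blocks never fall inside one merge window
    chrom_of_block = 1 + (np.arange(n_blocks) * 22) // max(n_blocks, 22)
    chrom_of_block = np.minimum(chrom_of_block, 22)
    chrom = chrom_of_block[block].astype(int)
    pos = np.empty(m, dtype=np.int64)
    offset_in_block = np.arange(m) - starts[block]
    cursor = {}
    block_base = np.empty(n_blocks, dtype=np.int64)
    for b in range(n_blocks):
        c = chrom_of_block[b]
        base = cursor.get(c, 1_000_000)
        block_base[b] = base
        cursor[c] = base + int(sizes[b]) * 10_000 + 1_000_000
    pos = block_base[block] + offset_in_block * 10_000

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    a1 = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    a2 = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    def stats(z: np.ndarray, n: int, trait: str) -> SummaryStats:
        df = pd.DataFrame(
            {"snp": snp, "chrom": chrom, "pos": pos, "a1": a1, "a2": a2,
             "z": z, "p": z_to_p(z), "n": float(n)}
        )
        return SummaryStats(df=df, trait=trait)

    truth = pd.DataFrame(
        {"snp": snp, "component": COMPONENTS[comp_block[block]],
         "beta1": beta1, "beta2": beta2, "block": block}
    )
    ld = LdReference.from_blocks(dict(zip(snp, block.tolist())), r2_within=config.r2_within)
    return SimulationResult(
        stats1=stats(z1, config.n1, "trait1"),
        stats2=stats(z2, config.n2, "trait2"),
        ld=ld,
        truth=truth,
        config=config,
    )
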