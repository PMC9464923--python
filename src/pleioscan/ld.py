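"""LD reference: pairwise r² lookups and LD-block assignment.

Two interchangeable backings are supported:

* a *pairwise* table (SNP_A, SNP_B, R2) — blocks are the connected components
  of the graph whose edges are pairs with r² > 0.1;
* a *block* table (SNP, BLOCK) with a single within-block r² value, which is
  the representation the synthetic generator emits (disjoint equicorrelated
  blocks).

Absent pairs are treated as r² = 0. Every SNP belongs to exactly one block;
SNPs never seen by the reference are treated as singleton blocks.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .exceptions import ConfigurationError

#: edges above this r² join SNPs into one pruning block
BLOCK_R2 = 0.1


class LdReference:
    """Pairwise r² and LD-block structure over a fixed SNP universe."""

    def __init__(
        self,
        block_of: Mapping[str, int],
        *,
        r2_within: float | None = None,
        pairs: Mapping[tuple[str, str], float] | None = None,
    ):
        if r2_within is None and pairs is None:
            raise ConfigurationError("LdReference needs r2_within or explicit pairs")
        if r2_within is not None and not (0.0 <= r2_within <= 1.0):
            raise ConfigurationError(f"r2_within must be in [0, 1], got {r2_within}")
        self.block_of: dict[str, int] = dict(block_of)
        self.r2_within = r2_within
        # adjacency: snp -> {partner: r2}
        self._adj: dict[str, dict[str, float]] = {}
        if pairs is not None:
            for (a, b), r2 in pairs.items():
                if not (0.0 <= r2 <= 1.0):
                    raise ConfigurationError(f"r² must be in [0, 1], got {r2} for ({a},{b})")
                self._adj.setdefault(a, {})[b] = r2
                self._adj.setdefault(b, {})[a] = r2
        self._members: dict[int, list[str]] = {}
        for snp, blk in self.block_of.items():
            self._members.setdefault(blk, []).append(snp)

    # ------------------------------------------------------------------ #
    # constructors
    # ------------------------------------------------------------------ #
    @classmethod
    def from_blocks(cls, block_of: Mapping[str, int], r2_within: float) -> "LdReference":
        """Disjoint equicorrelated blocks: r² = ``r2_within`` inside a block, 0 outside."""
        return cls(block_of, r2_within=r2_within)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str, float]],
        snp_ids: Sequence[str],
    ) -> "LdReference":
        """Build from explicit pairwise r²; blocks = components of the r² > 0.1 graph."""
        snp_ids = list(snp_ids)
        index = {s: i for i, s in enumerate(snp_ids)}
        pair_map: dict[tuple[str, str], float] = {}
        rows, cols = [], []
        for a, b, r2 in pairs:
            if a not in index or b not in index:
                raise ConfigurationError(f"pair ({a},{b}) references a SNP outside the universe")
            key = (a, b) if a <= b else (b, a)
            pair_map[key] = float(r2)
            if r2 > BLOCK_R2:
                rows.append(index[a])
                cols.append(index[b])
        n = len(snp_ids)
        graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        _, labels = connected_components(graph, directed=False)
        block_of = {s: int(labels[i]) for s, i in index.items()}
        return cls(block_of, pairs=pair_map)

    @classmethod
    def independent(cls, snp_ids: Sequence[str]) -> "LdReference":
        """Every SNP its own block, all r² = 0 (useful for already-pruned tables)."""
        return cls({s: i for i, s in enumerate(snp_ids)}, r2_within=0.0)

    # ------------------------------------------------------------------ #
    # queries
    # ------------------------------------------------------------------ #
    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        if self._adj:
            return self._adj.get(a, {}).get(b, 0.0)
        ba, bb = self.block_of.get(a), self.block_of.get(b)
        if ba is not None and ba == bb:
            return float(self.r2_within)
        return 0.0

    def neighbors(self, snp: str, min_r2: float) -> list[str]:
        """SNPs (excluding ``snp`` itself) with r² ≥ ``min_r2`` to ``snp``."""
        if self._adj:
            return [s for s, r2 in self._adj.get(snp, {}).items() if r2 >= min_r2]
        if self.r2_within is not None and self.r2_within >= min_r2:
            blk = self.block_of.get(snp)
            if blk is None:
                return []
            return [s for s in self._members[blk] if s != snp]
        return []

    def block_labels(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Integer block label per SNP; unknown SNPs get fresh singleton labels."""
        labels = np.empty(len(snp_ids), dtype=np.int64)
        fresh = (max(self.block_of.values()) + 1) if self.block_of else 0
        for i, s in enumerate(snp_ids):
            blk = self.block_of.get(s)
            if blk is None:
                blk = fresh
                fresh += 1
            labels[i] = blk
        return labels

    @property
    def n_blocks(self) -> int:
        return len(set(self.block_of.values()))

    # ------------------------------------------------------------------ #
    # file formats (tab-delimited, headers per the external interface)
    # ------------------------------------------------------------------ #
    def to_block_file(self, path) -> None:
        df = pd.DataFrame(
            {"SNP": list(self.block_of.keys()), "BLOCK": list(self.block_of.values())}
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, *, r2_within: float = 0.8) -> "LdReference":
        """Read either a pairwise file (SNP_A, SNP_B, R2) or a block file (SNP, BLOCK)."""
        df = pd.read_csv(path, sep="\t")
        cols = set(df.columns)
        if {"SNP_A", "SNP_B", "R2"} <= cols:
            snps = pd.unique(pd.concat([df["SNP_A"], df["SNP_B"]]))
            return cls.from_pairs(
                df[["SNP_A", "SNP_B", "R2"]].itertuples(index=False, name=None), list(snps)
            )
        if {"SNP", "BLOCK"} <= cols:
            return cls.from_blocks(dict(zip(df["SNP"], df["BLOCK"])), r2_within=r2_within)
        raise ConfigurationError(
            "LD file must have columns (SNP_A, SNP_B, R2) or (SNP, BLOCK); got "
            + ", ".join(df.columns)
        )
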