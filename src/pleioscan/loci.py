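"""Locus definition: independent significant SNPs, leads, candidates, merging,
effect-direction concordance and novelty classification.

The clumping protocol follows the standard SNP2GENE-style convention:

1. significant SNPs: FDR statistic < threshold (default 0.05);
2. *independent significant* SNPs: greedy selection by ascending statistic,
   discarding SNPs with r² >= 0.6 to an already chosen one;
3. *lead* SNPs: the subset of independent significant SNPs mutually r² < 0.1
   (same greedy order);
4. *candidate* SNPs: every SNP in the harmonized pair with r² >= 0.6 to a
   lead, regardless of its own FDR value;
5. loci whose candidate borders on one chromosome lie within 250 kb of each
   other are merged, keeping the best-statistic lead.

A locus is *novel* when its lead is significant, its original primary-GWAS
p-value exceeds 5e-8, and it is independent (r² < 0.6) of — and more than
250 kb away from — every previously reported SNP in the catalog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .condfdr import FdrAssignment
from .exceptions import ConfigurationError
from .ld import LdReference

logger = logging.getLogger(__name__)

CANDIDATE_R2 = 0.6
LEAD_R2 = 0.1
MERGE_DISTANCE = 250_000
NOVELTY_GWAS_P = 5e-8
NOVELTY_DISTANCE = 250_000


@dataclass
class Locus:
    """One genomic risk locus (a Table-1-style row)."""

    index: int
    lead_snp: str
    chrom: int
    lead_pos: int
    candidate_snps: list[str]
    start: int
    end: int
    lead_condfdr: float
    lead_conjfdr: float
    z_a: float
    z_b: float
    statistic: float = np.nan
    direction: str = ""
    novel: bool | None = None

    @property
    def n_candidates(self) -> int:
        return len(self.candidate_snps)


@dataclass
class KnownCatalog:
    """Previously reported SNPs used for novelty classification."""

    df: pd.DataFrame  # columns snp, chrom, pos

    @classmethod
    def from_records(cls, records: list[tuple[str, int, int]]) -> "KnownCatalog":
        return cls(pd.DataFrame(records, columns=["snp", "chrom", "pos"]))

    @classmethod
    def read(cls, path) -> "KnownCatalog":
        df = pd.read_csv(path, sep="\t")
        missing = {"SNP", "CHR", "BP"} - set(df.columns)
        if missing:
            raise ConfigurationError(f"catalog file missing columns: {sorted(missing)}")
        return cls(df.rename(columns={"SNP": "snp", "CHR": "chrom", "BP": "pos"})[
            ["snp", "chrom", "pos"]])

    def __len__(self) -> int:
        return len(self.df)


def _statistic_column(statistic: str) -> str:
    mapping = {"condfdr": "condfdr_ab", "condfdr_ab": "condfdr_ab",
               "condfdr_ba": "condfdr_ba", "conjfdr": "conjfdr"}
    if statistic not in mapping:
        raise ConfigurationError(f"statistic must be one of {sorted(mapping)}")
    return mapping[statistic]


def clump_loci(
    assignment: FdrAssignment,
    ld: LdReference,
    statistic: str = "condfdr",
    threshold: float = 0.05,
) -> list[Locus]:
    """Clump significant SNPs into loci (see module docstring for the protocol).

    Deterministic regardless of input row order: greedy selection is ordered
    by (statistic, chrom, pos, snp id).
    """
    df = assignment.df
    col = _statistic_column(statistic)
    sig = df.loc[df[col] < threshold]
    if len(sig) == 0:
        return []
    sig = sig.sort_values([col, "chrom", "pos", "snp"], kind="stable")

    # greedy independent significant SNPs (pairwise r² < 0.6)
    independent: list[str] = []
    chosen: set[str] = set()
    excluded: set[str] = set()
    for snp in sig["snp"]:
        if snp in excluded:
            continue
        independent.append(snp)
        chosen.add(snp)
        excluded.update(ld.neighbors(snp, CANDIDATE_R2))

    # leads: mutually r² < 0.1, same order
    leads: list[str] = []
    lead_excluded: set[str] = set()
    for snp in independent:
        if snp in lead_excluded:
            continue
        leads.append(snp)
        lead_excluded.update(ld.neighbors(snp, LEAD_R2))

    info = df.set_index("snp")
    pair_snps = set(df["snp"])

    loci: list[Locus] = []
    for lead in leads:
        cands = [s for s in ld.neighbors(lead, CANDIDATE_R2) if s in pair_snps]
        cands = [lead] + sorted(set(cands) - {lead})
        positions = info.loc[cands, "pos"]
        row = info.loc[lead]
        loci.append(
            Locus(
                index=-1,
                lead_snp=lead,
                chrom=int(row["chrom"]),
                lead_pos=int(row["pos"]),
                candidate_snps=cands,
                start=int(positions.min()),
                end=int(positions.max()),
                lead_condfdr=float(row["condfdr_ab"]),
                lead_conjfdr=float(row["conjfdr"]),
                z_a=float(row["z_a"]),
                z_b=float(row["z_b"]),
                statistic=float(row[col]),
            )
        )

    # merge loci whose candidate borders are within MERGE_DISTANCE on one chromosome
    loci.sort(key=lambda l: (l.chrom, l.start, l.lead_snp))
    merged: list[Locus] = []
    for locus in loci:
        last = merged[-1] if merged else None
        if last is not None and locus.chrom == last.chrom and locus.start - last.end < MERGE_DISTANCE:
            keep, other = (last, locus) if last.statistic <= locus.statistic else (locus, last)
            keep.candidate_snps = sorted(set(last.candidate_snps) | set(locus.candidate_snps))
            keep.start = min(last.start, locus.start)
            keep.end = max(last.end, locus.end)
            merged[-1] = keep
        else:
            merged.append(locus)

    for i, locus in enumerate(merged, start=1):
        locus.index = i
        locus.direction = classify_direction(locus)
    logger.info("clump_loci[%s<%g]: %d significant SNPs -> %d leads -> %d loci",
                statistic, threshold, len(sig), len(leads), len(merged))
    return merged


def classify_direction(locus: Locus) -> str:
    """Concordant when the lead's z-scores in the two traits share a sign."""
    if locus.z_a == 0 or locus.z_b == 0:
        return "undetermined"
    return "concordant" if np.sign(locus.z_a) * np.sign(locus.z_b) > 0 else "discordant"


def classify_novel(
    locus: Locus,
    original_p: float,
    catalog: KnownCatalog,
    ld: LdReference,
    threshold: float = 0.05,
) -> bool:
    """Novel iff significant, sub-genome-wide in the original GWAS, and both
    LD-independent (r² < 0.6) of and > 250 kb away from every catalog SNP."""
    if not (locus.statistic < threshold):
        return False
    if not (original_p > NOVELTY_GWAS_P):
        return False
    for row in catalog.df.itertuples(index=False):
        if ld.r2(locus.lead_snp, row.snp) >= CANDIDATE_R2:
            return False
        if row.chrom == locus.chrom and abs(row.pos - locus.lead_pos) <= NOVELTY_DISTANCE:
            return False
    return True


def annotate_novelty(
    loci: list[Locus],
    original_p: dict[str, float] | pd.Series,
    catalog: KnownCatalog,
    ld: LdReference,
    threshold: float = 0.05,
) -> list[Locus]:
    """Set ``novel`` on every locus from its lead's original primary-GWAS p."""
    for locus in loci:
        locus.novel = classify_novel(locus, float(original_p[locus.lead_snp]), catalog, ld,
                                     threshold)
    return loci


def loci_table(loci: list[Locus], gene_annotation: dict[str, str] | None = None) -> pd.DataFrame:
    """Tabular (Table-1-style) rendering of a locus list."""
    rows = []
    for l in loci:
        rows.append(
            {
                "LOCUS": l.index,
                "CHR_POS": f"{l.chrom}:{l.lead_pos}",
                "SNP": l.lead_snp,
                "NEAREST_GENE": (gene_annotation or {}).get(l.lead_snp, ""),
                "N_CANDIDATES": l.n_candidates,
                "START": l.start,
                "END": l.end,
                "CONDFDR": l.lead_condfdr,
                "CONJFDR": l.lead_conjfdr,
                "Z_A": l.z_a,
                "Z_B": l.z_b,
                "DIRECTION": l.direction,
                "NOVEL": l.novel,
            }
        )
    return pd.DataFrame(rows)
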