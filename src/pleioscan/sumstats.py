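"""Reading, validating and harmonizing GWAS summary statistics.

The on-disk dialect is tab-delimited with header columns
``SNP CHR BP A1 A2 Z P N`` (or ``BETA``/``SE`` in place of ``Z``).
A1 is the effect allele: ``z`` is the association z-score of A1 dosage.
Positions are 1-based (hg19 labels are nominal; no liftover is attempted).

Harmonization of two traits intersects on SNP id, re-signs the second
trait's z when its alleles are recorded in the swapped orientation, and
drops strand-ambiguous (A/T, C/G) SNPs and SNPs whose alleles cannot be
reconciled at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import z_to_p
from .exceptions import ConfigurationError, EmptyInputError

logger = logging.getLogger(__name__)

VALID_ALLELES = {"A", "C", "G", "T"}
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: canonical column order of the TSV dialect
SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "Z", "P", "N"]

#: |2·Φ(−|z|) − p| ≤ REL_TOL·p is required when both z and p are provided
ZP_REL_TOL = 0.1


@dataclass
class SummaryStats:
    """Validated per-SNP association records for one trait.

    ``df`` columns: snp, chrom, pos, a1, a2, z, p, n. SNP ids are unique,
    p ∈ (0, 1], a1 ≠ a2, and |z| is consistent with p within two-sided
    normal rounding tolerance.
    """

    df: pd.DataFrame
    trait: str = "trait"
    n_dropped: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def write(self, path) -> None:
        out = pd.DataFrame(
            {
                "SNP": self.df["snp"],
                "CHR": self.df["chrom"],
                "BP": self.df["pos"],
                "A1": self.df["a1"],
                "A2": self.df["a2"],
                "Z": self.df["z"],
                "P": self.df["p"],
                "N": self.df["n"],
            }
        )
        out.to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedPair:
    """Two traits aligned on shared SNPs with allele-consistent z signs.

    ``df`` columns: snp, chrom, pos, z_a, p_a, n_a, z_b, p_b, n_b.
    """

    df: pd.DataFrame
    trait_a: str = "a"
    trait_b: str = "b"
    n_dropped: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def z(self, trait: str) -> np.ndarray:
        return self.df[f"z_{self._key(trait)}"].to_numpy()

    def p(self, trait: str) -> np.ndarray:
        return self.df[f"p_{self._key(trait)}"].to_numpy()

    def _key(self, trait: str) -> str:
        if trait in ("a", self.trait_a):
            return "a"
        if trait in ("b", self.trait_b):
            return "b"
        raise ConfigurationError(f"unknown trait {trait!r} (have {self.trait_a}, {self.trait_b})")

    def replace(self, **columns) -> "HarmonizedPair":
        df = self.df.copy()
        for name, values in columns.items():
            df[name] = values
        return HarmonizedPair(df, self.trait_a, self.trait_b, dict(self.n_dropped))


def _validate_frame(df: pd.DataFrame, trait: str) -> tuple[pd.DataFrame, dict]:
    """Drop rows violating the record invariants; return kept rows and drop counts."""
    dropped: dict[str, int] = {}

    def drop(mask: pd.Series, reason: str) -> pd.DataFrame:
        n = int(mask.sum())
        if n:
            dropped[reason] = dropped.get(reason, 0) + n
            logger.info("%s: dropped %d rows (%s)", trait, n, reason)
        return df.loc[~mask]

    df = drop(df[["snp", "chrom", "pos", "a1", "a2", "z", "p", "n"]].isna().any(axis=1), "missing values")
    df = drop(df.duplicated(subset="snp", keep="first"), "duplicate snp id")
    df = drop(~df["chrom"].isin(range(1, 23)), "chromosome outside 1-22")
    df = drop(df["pos"] < 1, "non-positive position")
    a1 = df["a1"].str.upper()
    a2 = df["a2"].str.upper()
    df = df.assign(a1=a1, a2=a2)
    df = drop(~(df["a1"].isin(VALID_ALLELES) & df["a2"].isin(VALID_ALLELES)), "non-ACGT allele")
    df = drop(df["a1"] == df["a2"], "identical alleles")
    df = drop((df["p"] <= 0) | (df["p"] > 1), "p outside (0,1]")
    implied = z_to_p(df["z"].to_numpy())
    df = drop(
        pd.Series(np.abs(implied - df["p"].to_numpy()) > ZP_REL_TOL * df["p"].to_numpy(), index=df.index),
        "z/p inconsistent",
    )
    return df.reset_index(drop=True), dropped


def read_sumstats(path, columns: dict | None = None, trait: str | None = None) -> SummaryStats:
    """Read a tab-delimited summary-statistics file into a validated table.

    Parameters
    ----------
    path : file path
        TSV with header ``SNP CHR BP A1 A2 Z P N``; ``BETA`` + ``SE`` may
        replace ``Z`` (z = beta/SE), and ``P`` may be absent (p = 2·Φ(−|z|)).
    columns : mapping, optional
        Overrides mapping canonical names to the file's actual column names,
        e.g. ``{"SNP": "rsid", "P": "pval"}``.
    trait : str, optional
        Label carried through downstream outputs; defaults to the file stem.
    """
    raw = pd.read_csv(path, sep="\t")
    if columns:
        rename = {actual: canon for canon, actual in columns.items()}
        missing_override = [a for a in rename if a not in raw.columns]
        if missing_override:
            raise ConfigurationError(f"column overrides not found in file: {missing_override}")
        raw = raw.rename(columns=rename)

    mandatory = ["SNP", "CHR", "BP", "A1", "A2", "N"]
    missing = [c for c in mandatory if c not in raw.columns]
    if missing:
        raise ConfigurationError(f"missing mandatory columns: {missing}")
    if "Z" not in raw.columns:
        if {"BETA", "SE"} <= set(raw.columns):
            with np.errstate(divide="ignore", invalid="ignore"):
                raw["Z"] = raw["BETA"] / raw["SE"]
        else:
            raise ConfigurationError("need either Z or both BETA and SE")
    if "P" not in raw.columns:
        raw["P"] = z_to_p(raw["Z"].to_numpy())

    df = pd.DataFrame(
        {
            "snp": raw["SNP"].astype(str),
            "chrom": pd.to_numeric(raw["CHR"], errors="coerce"),
            "pos": pd.to_numeric(raw["BP"], errors="coerce"),
            "a1": raw["A1"].astype(str),
            "a2": raw["A2"].astype(str),
            "z": pd.to_numeric(raw["Z"], errors="coerce"),
            "p": pd.to_numeric(raw["P"], errors="coerce"),
            "n": pd.to_numeric(raw["N"], errors="coerce"),
        }
    )
    trait = trait or getattr(path, "stem", None) or str(path)
    df, dropped = _validate_frame(df, trait)
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no valid summary-statistic rows (dropped: {dropped})")
    df["chrom"] = df["chrom"].astype(int)
    df["pos"] = df["pos"].astype(int)
    return SummaryStats(df=df, trait=trait, n_dropped=dropped)


def harmonize(a: SummaryStats, b: SummaryStats) -> HarmonizedPair:
    """Align two traits on shared SNPs with a consistent effect allele.

    When b's (a1, a2) equal a's (a2, a1) the sign of z_b is flipped; SNPs
    whose alleles mismatch entirely, and strand-ambiguous (A/T, C/G) SNPs,
    are dropped and counted. Idempotent on an already-aligned pair.
    """
    merged = a.df.merge(b.df, on="snp", suffixes=("_a", "_b"), how="inner")
    dropped: dict[str, int] = {}
    if len(merged) == 0:
        raise EmptyInputError(
            f"no shared SNPs between {a.trait} ({len(a)} SNPs) and {b.trait} ({len(b)} SNPs)"
        )

    ambiguous = [
        (x, y) in AMBIGUOUS_PAIRS
        for x, y in zip(merged["a1_a"], merged["a2_a"])
    ]
    ambiguous = np.array(ambiguous) | np.array(
        [(x, y) in AMBIGUOUS_PAIRS for x, y in zip(merged["a1_b"], merged["a2_b"])]
    )
    same = (merged["a1_a"] == merged["a1_b"]) & (merged["a2_a"] == merged["a2_b"])
    swapped = (merged["a1_a"] == merged["a2_b"]) & (merged["a2_a"] == merged["a1_b"])
    mismatch = ~(same | swapped)

    dropped["strand_ambiguous"] = int(ambiguous.sum())
    dropped["allele_mismatch"] = int((mismatch & ~ambiguous).sum())
    keep = ~(ambiguous | mismatch.to_numpy())
    if dropped["strand_ambiguous"] or dropped["allele_mismatch"]:
        logger.info(
            "harmonize: dropped %d strand-ambiguous and %d allele-mismatched SNPs",
            dropped["strand_ambiguous"],
            dropped["allele_mismatch"],
        )
    merged = merged.loc[keep]
    if len(merged) == 0:
        raise EmptyInputError("no SNPs survived allele harmonization")

    sign = np.where(merged["a1_a"] == merged["a1_b"], 1.0, -1.0)
    df = pd.DataFrame(
        {
            "snp": merged["snp"].to_numpy(),
            "chrom": merged["chrom_a"].to_numpy(),
            "pos": merged["pos_a"].to_numpy(),
            "z_a": merged["z_a"].to_numpy(),
            "p_a": merged["p_a"].to_numpy(),
            "n_a": merged["n_a"].to_numpy(),
            "z_b": merged["z_b"].to_numpy() * sign,
            "p_b": merged["p_b"].to_numpy(),
            "n_b": merged["n_b"].to_numpy(),
        }
    ).reset_index(drop=True)
    return HarmonizedPair(df=df, trait_a=a.trait, trait_b=b.trait, n_dropped=dropped)
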