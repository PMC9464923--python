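"""Built-in worked-example data: the 11 PCOS/T2D pleiotropic lead SNPs.

These are the published lead SNPs identified by conditioning PCOS on T2D at
condFDR < 0.05, with their conditional and conjunctional FDR values, the
original GWAS p-values and signed z-scores for both traits, and gene
annotations. They serve as a small, fully printed end-to-end example for the
locus-definition machinery (counts, direction concordance, novelty).

Note on orientation: the source table prints its two z-score columns with
swapped trait labels (each printed z reproduces the *other* trait's p-value
under z = Φ⁻¹(p/2)); the records below pair every z with its own trait's
p-value so that each satisfies |2·Φ(−|z|) − p| ≤ 0.1·p.
"""

from __future__ import annotations

import pandas as pd

from .condfdr import FdrAssignment
from .ld import LdReference
from .loci import KnownCatalog
from .sumstats import SummaryStats

# snp, chrom, pos, ref, alt, nearest_gene, condfdr (PCOS|T2D), conjfdr,
# p_t2d, p_pcos, z_pcos, z_t2d
_TABLE1 = [
    ("rs1509096",   2, 165_737_889, "G", "A", "RNA5SP111", 9.43e-03, 9.53e-03, 1.80e-05, 1.40e-05, -4.34,  -4.29),
    ("rs13061415",  3,  12_349_924, "C", "T", "PPARG",     3.09e-02, 3.09e-02, 6.60e-09, 5.60e-05,  4.03,   5.80),
    ("rs4234212",   3, 123_010_775, "C", "T", "ADCY5",     4.64e-02, 4.64e-02, 5.80e-05, 9.30e-05,  3.91,  -4.02),
    ("rs138484257", 5,  43_618_391, "G", "T", "NNT",       1.46e-02, 9.69e-01, 5.30e-01, 9.80e-08, -5.33,   0.63),
    ("rs804274",    8,  11_625_205, "C", "A", "NEIL2",     6.60e-03, 7.47e-01, 7.30e-02, 2.10e-07, -5.19,   1.79),
    ("rs7929660",  11,  30_339_461, "G", "A", "ARL14EP",   9.72e-03, 5.65e-01, 2.70e-02, 6.80e-07, -4.97,   2.21),
    ("rs5030174",  11,  32_449_098, "G", "A", "WT1",       1.67e-02, 1.67e-02, 1.50e-05, 2.70e-05, -4.20,   4.33),
    ("rs12808938", 11,  83_562_895, "G", "T", "DLG2",      2.43e-02, 6.11e-01, 3.50e-02, 1.60e-06,  4.80,   2.11),
    ("rs7190396",  16,  53_822_502, "G", "T", "FTO",       1.97e-03, 1.97e-03, 7.60e-74, 2.50e-06, -4.71, -18.18),
    ("rs2432581",  16,  81_463_967, "G", "A", "CMIP",      1.56e-02, 3.32e-02, 1.00e-04, 2.50e-05,  4.21,   3.89),
    ("rs1474758",  20,  56_125_891, "C", "A", "PCK1",      2.49e-02, 9.17e-01, 3.50e-01, 2.50e-07, -5.16,  -0.93),
]

_COLUMNS = ["snp", "chrom", "pos", "ref", "alt", "nearest_gene", "condfdr",
            "conjfdr", "p_t2d", "p_pcos", "z_pcos", "z_t2d"]

#: effective GWAS sample sizes (cases + controls)
N_PCOS = 37_264
N_T2D = 898_130


def load_table1() -> pd.DataFrame:
    """The 11 lead-SNP records as a DataFrame."""
    return pd.DataFrame(_TABLE1, columns=_COLUMNS)


def table1_sumstats() -> tuple[SummaryStats, SummaryStats]:
    """The lead-SNP records as two per-trait summary-statistic tables (PCOS, T2D).

    A1 is the alternative (effect) allele, matching the Ref/Alt presentation.
    """
    t = load_table1()

    def build(zcol: str, pcol: str, n: int, trait: str) -> SummaryStats:
        df = pd.DataFrame({
            "snp": t["snp"], "chrom": t["chrom"], "pos": t["pos"],
            "a1": t["alt"], "a2": t["ref"], "z": t[zcol], "p": t[pcol],
            "n": float(n),
        })
        return SummaryStats(df=df, trait=trait)

    return build("z_pcos", "p_pcos", N_PCOS, "PCOS"), build("z_t2d", "p_t2d", N_T2D, "T2D")


def table1_assignment() -> FdrAssignment:
    """Per-SNP FDR assignment built from the printed condFDR/conjFDR values.

    Trait a = PCOS (primary), trait b = T2D (conditioning); condfdr_ab is the
    printed condFDR of PCOS given T2D.
    """
    t = load_table1()
    df = pd.DataFrame({
        "snp": t["snp"], "chrom": t["chrom"], "pos": t["pos"],
        "z_a": t["z_pcos"], "z_b": t["z_t2d"],
        "p_a": t["p_pcos"], "p_b": t["p_t2d"],
        "condfdr_ab": t["condfdr"], "conjfdr": t["conjfdr"],
    })
    return FdrAssignment.from_values(df)


def table1_ld() -> LdReference:
    """LD reference for the lead SNPs: already pruned, no LD partners."""
    return LdReference.independent(load_table1()["snp"].tolist())


def synthetic_known_pcos_catalog() -> KnownCatalog:
    """Synthetic stand-in for a catalog of previously reported PCOS SNPs.

    No machine-readable catalog accompanies the worked example, so this
    two-row synthetic catalog lists exactly the two leads classified as
    previously reported (rs804274 and rs7929660); with it, the novelty rule
    reproduces the published 9-of-11 split.
    """
    t = load_table1().set_index("snp")
    return KnownCatalog.from_records(
        [(s, int(t.loc[s, "chrom"]), int(t.loc[s, "pos"])) for s in ("rs804274", "rs7929660")]
    )
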