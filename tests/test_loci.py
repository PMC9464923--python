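"""Locus clumping, merging, direction concordance and novelty."""

import numpy as np
import pandas as pd
import pytest

from pleioscan import (KnownCatalog, LdReference, annotate_novelty,
                       classify_direction, classify_novel, clump_loci,
                       harmonize, loci_table)
from pleioscan.condfdr import CondFdr, FdrAssignment
from pleioscan.datasets import synthetic_known_pcos_catalog
from pleioscan.loci import Locus


def _assignment(snps, positions, stats, chrom=1, z_a=None, z_b=None):
    n = len(snps)
    df = pd.DataFrame({
        "snp": snps, "chrom": chrom, "pos": positions,
        "z_a": z_a if z_a is not None else np.full(n, 2.0),
        "z_b": z_b if z_b is not None else np.full(n, 2.0),
        "p_a": np.full(n, 1e-4), "p_b": np.full(n, 1e-4),
        "condfdr_ab": stats, "conjfdr": stats,
    })
    return FdrAssignment.from_values(df)


class TestClumping:
    def test_hand_enumerated_five_snp_example(self):
        # s1..s5 at 100 kb spacing; r²(s1,s2)=0.7, r²(s4,s5)=0.05, rest 0;
        # statistics {0.01, 0.02, 0.2, 0.03, 0.04} at threshold 0.05
        snps = [f"s{i}" for i in range(1, 6)]
        assignment = _assignment(snps, [100_000 * i for i in range(1, 6)],
                                 [0.01, 0.02, 0.2, 0.03, 0.04])
        ld = LdReference.from_pairs(
            [("s1", "s2", 0.7), ("s4", "s5", 0.05)], snps)
        loci = clump_loci(assignment, ld, "condfdr", 0.05)
        # leads {s1, s4, s5}; inter-locus gaps < 250 kb merge all into one locus
        assert len(loci) == 1
        locus = loci[0]
        assert locus.lead_snp == "s1"
        assert sorted(locus.candidate_snps) == ["s1", "s2", "s4", "s5"]
        assert (locus.start, locus.end) == (100_000, 500_000)

    def test_singleton_locus(self):
        assignment = _assignment(["s1"], [100_000], [0.01])
        ld = LdReference.independent(["s1"])
        loci = clump_loci(assignment, ld, "condfdr", 0.05)
        assert len(loci) == 1
        assert loci[0].candidate_snps == ["s1"]
        assert loci[0].start == loci[0].end == 100_000

    def test_no_significant_snps_returns_empty(self):
        assignment = _assignment(["s1", "s2"], [1, 300_000], [0.5, 0.9])
        ld = LdReference.independent(["s1", "s2"])
        assert clump_loci(assignment, ld, "condfdr", 0.05) == []

    def test_gap_of_exactly_250kb_not_merged(self):
        assignment = _assignment(["s1", "s2"], [100_000, 350_000], [0.01, 0.02])
        ld = LdReference.independent(["s1", "s2"])
        assert len(clump_loci(assignment, ld, "condfdr", 0.05)) == 2
        assignment = _assignment(["s1", "s2"], [100_000, 349_999], [0.01, 0.02])
        assert len(clump_loci(assignment, ld, "condfdr", 0.05)) == 1

    def test_lead_and_independent_r2_invariants(self, overlap_sim):
        pair = harmonize(overlap_sim.stats1, overlap_sim.stats2)
        res = CondFdr(pair, overlap_sim.ld).fit(iterations=20, seed=5)
        loci = clump_loci(res.assignment, overlap_sim.ld, "condfdr", 0.05)
        assert loci, "simulation with strong shared signal should yield loci"
        leads = [l.lead_snp for l in loci]
        for i, a in enumerate(leads):
            for b in leads[i + 1:]:
                assert overlap_sim.ld.r2(a, b) < 0.1
        for l in loci:
            for cand in l.candidate_snps:
                assert any(overlap_sim.ld.r2(cand, lead) >= 0.6 or cand == lead
                           for lead in leads if lead in l.candidate_snps) or cand == l.lead_snp

    def test_order_independence(self):
        snps = [f"s{i}" for i in range(1, 6)]
        stats = [0.01, 0.02, 0.2, 0.03, 0.04]
        assignment = _assignment(snps, [100_000 * i for i in range(1, 6)], stats)
        ld = LdReference.from_pairs([("s1", "s2", 0.7), ("s4", "s5", 0.05)], snps)
        base = clump_loci(assignment, ld, "condfdr", 0.05)
        shuffled = FdrAssignment.from_values(
            assignment.df.sample(frac=1.0, random_state=3).reset_index(drop=True))
        again = clump_loci(shuffled, ld, "condfdr", 0.05)
        assert [(l.lead_snp, l.start, l.end, tuple(l.candidate_snps)) for l in base] == \
               [(l.lead_snp, l.start, l.end, tuple(l.candidate_snps)) for l in again]


class TestTable1Counts:
    def test_condfdr_threshold_yields_11_loci(self, table1_fdr, table1_ld_ref):
        loci = clump_loci(table1_fdr, table1_ld_ref, "condfdr", 0.05)
        assert len(loci) == 11
        assert all(l.n_candidates == 1 for l in loci)

    def test_conjfdr_threshold_yields_6_loci(self, table1_fdr, table1_ld_ref):
        loci = clump_loci(table1_fdr, table1_ld_ref, "conjfdr", 0.05)
        assert len(loci) == 6

    def test_printed_rows_satisfy_max_rule(self, table1_fdr):
        df = table1_fdr.df
        assert (df["conjfdr"] >= df["condfdr_ab"] - 1e-12).all()


class TestDirection:
    def test_concordant_example(self):
        locus = Locus(1, "rs1509096", 2, 165_737_889, ["rs1509096"],
                      165_737_889, 165_737_889, 9.43e-3, 9.53e-3, -4.34, -4.29)
        assert classify_direction(locus) == "concordant"

    def test_discordant_example(self):
        locus = Locus(3, "rs4234212", 3, 123_010_775, ["rs4234212"],
                      123_010_775, 123_010_775, 4.64e-2, 4.64e-2, -4.02, 3.91)
        assert classify_direction(locus) == "discordant"

    def test_zero_z_is_undetermined(self):
        locus = Locus(1, "s", 1, 1, ["s"], 1, 1, 0.01, 0.01, 0.0, 1.0)
        assert classify_direction(locus) == "undetermined"

    def test_table1_six_concordant_five_discordant(self, table1_fdr, table1_ld_ref):
        loci = clump_loci(table1_fdr, table1_ld_ref, "condfdr", 0.05)
        directions = [l.direction for l in loci]
        assert directions.count("concordant") == 6
        assert directions.count("discordant") == 5


class TestNovelty:
    @pytest.fixture()
    def table1_loci(self, table1_fdr, table1_ld_ref):
        return clump_loci(table1_fdr, table1_ld_ref, "condfdr", 0.05)

    def test_sub_threshold_lead_far_from_catalog_is_novel(self, table1_loci, table1_ld_ref):
        locus = next(l for l in table1_loci if l.lead_snp == "rs13061415")
        assert classify_novel(locus, 5.60e-5, synthetic_known_pcos_catalog(), table1_ld_ref)

    def test_lead_in_catalog_is_not_novel(self, table1_loci, table1_ld_ref):
        locus = next(l for l in table1_loci if l.lead_snp == "rs804274")
        assert not classify_novel(locus, 2.10e-7, synthetic_known_pcos_catalog(), table1_ld_ref)

    def test_genome_wide_significant_lead_is_not_novel(self, table1_loci, table1_ld_ref):
        locus = table1_loci[0]
        assert not classify_novel(locus, 1e-9, KnownCatalog.from_records([]), table1_ld_ref)

    def test_table1_nine_of_eleven_novel(self, table1_fdr, table1_loci, table1_ld_ref):
        original_p = table1_fdr.df.set_index("snp")["p_a"]
        annotate_novelty(table1_loci, original_p, synthetic_known_pcos_catalog(), table1_ld_ref)
        assert sum(l.novel for l in table1_loci) == 9
        not_novel = {l.lead_snp for l in table1_loci if not l.novel}
        assert not_novel == {"rs804274", "rs7929660"}


def test_loci_table_columns(table1_fdr, table1_ld_ref):
    loci = clump_loci(table1_fdr, table1_ld_ref, "condfdr", 0.05)
    table = loci_table(loci, gene_annotation={"rs7190396": "FTO"})
    assert len(table) == 11
    assert set(table.loc[table.SNP == "rs7190396", "NEAREST_GENE"]) == {"FTO"}
    assert {"LOCUS", "CHR_POS", "CONDFDR", "CONJFDR", "DIRECTION", "NOVEL"} <= set(table.columns)
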