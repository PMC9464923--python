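"""Conditional and conjunctional FDR estimation."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_pair
from pleioscan import ConfigurationError, LdReference, assign_fdr, build_fdr_grid, harmonize
from pleioscan.condfdr import CondFdr, FdrAssignment, conditional_fdr_curve
from pleioscan.simulate import SimulationConfig, simulate


class TestConditionalFdrCurve:
    def test_stratum_enumeration_example(self):
        # stratum {0.01, 0.02, 0.9}: condFDR at p=0.01 is 0.01/(1/3) = 0.03
        p = np.array([0.01, 0.02, 0.9])
        out = conditional_fdr_curve(p, np.ones(3, bool), np.array([0.01]))
        assert out[0] == pytest.approx(0.03)

    def test_rank_one_is_bh_like(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        pmin = p.min()
        out = conditional_fdr_curve(p, np.ones(50, bool), np.array([pmin]))
        assert out[0] == pytest.approx(min(1.0, 50 * pmin))

    def test_p_equal_one_gives_one(self):
        p = np.array([0.2, 0.5, 1.0])
        out = conditional_fdr_curve(p, np.ones(3, bool), np.array([1.0]))
        assert out[0] == 1.0

    def test_invariant_to_duplicating_snp_set(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        evalp = np.array([0.01, 0.05, 0.2])
        once = conditional_fdr_curve(p, np.ones(200, bool), evalp)
        twice = conditional_fdr_curve(np.tile(p, 2), np.ones(400, bool), evalp)
        np.testing.assert_allclose(once, twice)


class TestFdrGrid:
    @pytest.fixture(scope="class")
    def sim_pair(self):
        sim = simulate(SimulationConfig(m=20_000, block_size=1, seed=21))
        return harmonize(sim.stats1, sim.stats2), sim.ld

    def test_grid_matches_direct_formula_at_nodes(self, sim_pair):
        pair, ld = sim_pair
        grid = build_fdr_grid(pair, ld, "a", iterations=1, seed=0)
        p1 = pair.df["p_a"].to_numpy()
        p2 = pair.df["p_b"].to_numpy()
        for xi, xj in [(1.0, 0.0), (2.0, 1.0), (3.0, 0.5)]:
            i = np.searchsorted(grid.primary_edges, xi)
            j = np.searchsorted(grid.cond_edges, xj)
            direct = conditional_fdr_curve(p1, p2 <= 10.0 ** (-xj), np.array([10.0 ** (-xi)]))[0]
            # grid is monotonized afterwards, so the cell can only be >= direct
            assert grid.values[i, j] >= direct - 1e-12
            assert grid.values[i, j] == pytest.approx(direct, rel=0.05)

    def test_monotone_in_primary_p(self, sim_pair):
        pair, ld = sim_pair
        grid = build_fdr_grid(pair, ld, "a", iterations=2, seed=0)
        # condFDR non-increasing as -log10 p grows (non-decreasing with p)
        assert np.all(np.diff(grid.values, axis=0) <= 1e-12)

    def test_values_in_unit_interval(self, sim_pair):
        pair, ld = sim_pair
        grid = build_fdr_grid(pair, ld, "a", iterations=2, seed=0)
        assert np.all(grid.values > 0) and np.all(grid.values <= 1)

    def test_independent_conditioning_matches_unconditional(self):
        # with π12 = 0 the conditioning stratum is uninformative: the grid
        # column at any threshold equals the unconditional column within
        # Monte-Carlo tolerance (where strata are well populated)
        sim = simulate(SimulationConfig(m=50_000, block_size=1, pi12=0.0, seed=31))
        pair = harmonize(sim.stats1, sim.stats2)
        grid = build_fdr_grid(pair, sim.ld, "a", iterations=1, seed=0)
        j0 = 0
        j1 = np.searchsorted(grid.cond_edges, 1.0)   # stratum p2 <= 0.1, ~5000 SNPs
        rows = slice(np.searchsorted(grid.primary_edges, 1.0),
                     np.searchsorted(grid.primary_edges, 3.0))
        ratio = grid.values[rows, j1] / grid.values[rows, j0]
        assert np.median(np.abs(np.log(ratio))) < 0.25

    def test_empty_tight_columns_inherit_looser(self):
        rng = np.random.default_rng(2)
        pair = make_pair(rng.standard_normal(500), np.full(500, 0.5))  # no p_b below ~0.6
        ld = LdReference.independent(pair.df["snp"].tolist())
        grid = build_fdr_grid(pair, ld, "a", iterations=2, seed=0)
        j_loose = 0
        j_tight = len(grid.cond_edges) - 1
        np.testing.assert_allclose(grid.values[:, j_tight], grid.values[:, j_loose])


class TestAssignFdr:
    @pytest.fixture(scope="class")
    def assignment(self, overlap_sim):
        pair = harmonize(overlap_sim.stats1, overlap_sim.stats2)
        res = CondFdr(pair, overlap_sim.ld).fit(iterations=20, seed=5)
        return res.assignment

    def test_max_rule_exact_for_every_snp(self, assignment):
        df = assignment.df
        np.testing.assert_array_equal(
            df["conjfdr"], np.maximum(df["condfdr_ab"], df["condfdr_ba"])
        )

    def test_all_values_in_unit_interval(self, assignment):
        df = assignment.df
        for col in ("condfdr_ab", "condfdr_ba", "conjfdr"):
            assert df[col].between(0, 1, inclusive="right").all()

    def test_threshold_nesting(self, assignment):
        df = assignment.df
        tight = set(df.loc[df["conjfdr"] < 0.01, "snp"])
        loose = set(df.loc[df["conjfdr"] < 0.05, "snp"])
        assert tight <= loose

    def test_out_of_grid_snp_clamped(self, caplog):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(1000)
        z[0] = 8.0  # p ~ 1e-15, beyond the -log10 p = 10 grid edge
        z_b = rng.standard_normal(1000)
        z_b[0] = 0.0  # conditioning coordinate sits exactly at the loosest column
        pair = make_pair(z, z_b)
        ld = LdReference.independent(pair.df["snp"].tolist())
        gab = build_fdr_grid(pair, ld, "a", iterations=1, seed=0)
        gba = build_fdr_grid(pair, ld, "b", iterations=1, seed=0)
        with caplog.at_level("WARNING"):
            assignment = assign_fdr(pair, gab, gba)
        assert "clamped" in caplog.text
        assert assignment.df.loc[0, "condfdr_ab"] == pytest.approx(
            gab.values[-1, 0], rel=1e-6)

    def test_equal_condfdrs_give_equal_conjfdr(self):
        df = pd.DataFrame({
            "snp": ["rs1"], "chrom": [1], "pos": [100], "z_a": [2.0], "z_b": [2.0],
            "p_a": [0.0455], "p_b": [0.0455],
            "condfdr_ab": [0.3], "condfdr_ba": [0.3], "conjfdr": [0.3]})
        a = FdrAssignment.from_values(df)
        assert a.df.loc[0, "conjfdr"] == 0.3

    def test_from_values_rejects_violated_max_rule(self):
        df = pd.DataFrame({
            "snp": ["rs1"], "chrom": [1], "pos": [100], "z_a": [2.0], "z_b": [2.0],
            "p_a": [0.0455], "p_b": [0.0455],
            "condfdr_ab": [0.5], "condfdr_ba": [0.5], "conjfdr": [0.3]})
        with pytest.raises(ConfigurationError):
            FdrAssignment.from_values(df)


def test_model_results_summary(overlap_sim):
    pair = harmonize(overlap_sim.stats1, overlap_sim.stats2)
    res = CondFdr(pair, overlap_sim.ld).fit(iterations=10, seed=5)
    text = res.summary()
    assert "conjFDR" in text and str(len(pair)) in text
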