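"""IO, validation and allele harmonization of summary statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pleioscan import (ConfigurationError, EmptyInputError, harmonize,
                       read_sumstats)
from pleioscan.datasets import table1_sumstats
from pleioscan.simulate import SimulationConfig, simulate
from pleioscan.sumstats import SummaryStats


@pytest.fixture()
def table1_files(tmp_path):
    pcos, t2d = table1_sumstats()
    p_path = tmp_path / "pcos.tsv"
    t_path = tmp_path / "t2d.tsv"
    pcos.write(p_path)
    t2d.write(t_path)
    return p_path, t_path


class TestReadSumstats:
    def test_reads_all_lead_snp_records(self, table1_files):
        p_path, t_path = table1_files
        pcos = read_sumstats(p_path, trait="PCOS")
        t2d = read_sumstats(t_path, trait="T2D")
        assert len(pcos) == 11 and len(t2d) == 11
        t2d_row = t2d.df.set_index("snp").loc["rs13061415"]
        assert t2d_row["p"] == pytest.approx(6.60e-9)
        assert t2d_row["z"] == pytest.approx(5.80)
        pcos_row = pcos.df.set_index("snp").loc["rs13061415"]
        assert pcos_row["p"] == pytest.approx(5.60e-5)

    def test_header_only_file_is_empty_input(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("SNP\tCHR\tBP\tA1\tA2\tZ\tP\tN\n")
        with pytest.raises(EmptyInputError):
            read_sumstats(path)

    def test_round_trip_is_identical(self, table1_files, tmp_path):
        stats = read_sumstats(table1_files[0])
        out = tmp_path / "again.tsv"
        stats.write(out)
        again = read_sumstats(out)
        pd.testing.assert_frame_equal(stats.df, again.df)
        assert table1_files[0].read_text() == out.read_text()

    def test_beta_se_converted_and_p_derived(self, tmp_path):
        path = tmp_path / "beta.tsv"
        pd.DataFrame(
            {"SNP": ["rs1"], "CHR": [1], "BP": [100], "A1": ["A"], "A2": ["G"],
             "BETA": [0.4], "SE": [0.1], "N": [1000]}
        ).to_csv(path, sep="\t", index=False)
        stats = read_sumstats(path)
        assert stats.df.loc[0, "z"] == pytest.approx(4.0)
        assert stats.df.loc[0, "p"] == pytest.approx(6.33e-5, rel=1e-3)

    def test_column_overrides(self, tmp_path):
        path = tmp_path / "alt.tsv"
        pd.DataFrame(
            {"rsid": ["rs1"], "CHR": [1], "BP": [100], "A1": ["A"], "A2": ["G"],
             "Z": [1.0], "pval": [0.3173], "N": [1000]}
        ).to_csv(path, sep="\t", index=False)
        stats = read_sumstats(path, columns={"SNP": "rsid", "P": "pval"})
        assert stats.df.loc[0, "snp"] == "rs1"

    def test_missing_mandatory_column_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"SNP": ["rs1"], "CHR": [1], "BP": [100], "Z": [1.0],
                      "P": [0.3], "N": [10]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ConfigurationError):
            read_sumstats(path)

    def test_invalid_rows_dropped_with_counts(self, tmp_path):
        path = tmp_path / "mixed.tsv"
        pd.DataFrame(
            {"SNP": ["rs1", "rs1", "rs2", "rs3", "rs4"],
             "CHR": [1, 1, 25, 2, 2],
             "BP": [100, 100, 100, 200, 300],
             "A1": ["A", "A", "A", "G", "G"],
             "A2": ["G", "G", "G", "G", "T"],
             "Z": [1.0, 1.0, 1.0, 1.0, 1.0],
             "P": [0.3173, 0.3173, 0.3173, 0.3173, 0.9],  # rs4: z/p inconsistent
             "N": [10, 10, 10, 10, 10]}
        ).to_csv(path, sep="\t", index=False)
        stats = read_sumstats(path)
        assert stats.df["snp"].tolist() == ["rs1"]
        assert stats.n_dropped["duplicate snp id"] == 1
        assert stats.n_dropped["chromosome outside 1-22"] == 1
        assert stats.n_dropped["identical alleles"] == 1
        assert stats.n_dropped["z/p inconsistent"] == 1


def _stats(records, trait="x"):
    df = pd.DataFrame(records, columns=["snp", "chrom", "pos", "a1", "a2", "z", "p", "n"])
    return SummaryStats(df=df, trait=trait)


class TestHarmonize:
    def test_allele_swap_negates_z(self):
        a = _stats([("rs1", 1, 100, "G", "A", 2.0, 0.0455, 100)])
        b = _stats([("rs1", 1, 100, "A", "G", 1.5, 0.1336, 100)])
        pair = harmonize(a, b)
        assert pair.df.loc[0, "z_b"] == pytest.approx(-1.5)
        assert pair.df.loc[0, "z_a"] == pytest.approx(2.0)

    def test_strand_ambiguous_dropped(self):
        a = _stats([("rs1", 1, 100, "A", "T", 2.0, 0.0455, 100),
                    ("rs2", 1, 200, "A", "G", 1.0, 0.3173, 100)])
        b = _stats([("rs1", 1, 100, "A", "T", 2.0, 0.0455, 100),
                    ("rs2", 1, 200, "A", "G", 1.0, 0.3173, 100)])
        pair = harmonize(a, b)
        assert pair.df["snp"].tolist() == ["rs2"]
        assert pair.n_dropped["strand_ambiguous"] == 1

    def test_full_allele_mismatch_dropped(self):
        a = _stats([("rs1", 1, 100, "A", "G", 2.0, 0.0455, 100)])
        b = _stats([("rs1", 1, 100, "C", "T", 2.0, 0.0455, 100)])
        with pytest.raises(EmptyInputError):
            harmonize(a, b)

    def test_empty_intersection_raises(self):
        a = _stats([("rs1", 1, 100, "A", "G", 2.0, 0.0455, 100)])
        b = _stats([("rs2", 1, 100, "A", "G", 2.0, 0.0455, 100)])
        with pytest.raises(EmptyInputError):
            harmonize(a, b)

    def test_idempotent_on_aligned_pair(self):
        sim = simulate(SimulationConfig(m=500, block_size=1, seed=1))
        once = harmonize(sim.stats1, sim.stats2)
        np.testing.assert_array_equal(once.df["z_b"], sim.stats2.df["z"])

    def test_permuted_alleles_recovered_exactly(self):
        """Generator-bookkeeping oracle: randomly swapping allele order in b
        (negating its z accordingly) must be undone by harmonization."""
        sim = simulate(SimulationConfig(m=1000, block_size=1, seed=3))
        truth_z = sim.stats2.df["z"].to_numpy().copy()
        rng = np.random.default_rng(7)
        flip = rng.random(1000) < 0.5
        b = sim.stats2.df.copy()
        b.loc[flip, ["a1", "a2"]] = b.loc[flip, ["a2", "a1"]].to_numpy()
        b.loc[flip, "z"] = -b.loc[flip, "z"]
        pair = harmonize(sim.stats1, SummaryStats(df=b, trait="b"))
        assert len(pair) == 1000
        np.testing.assert_allclose(pair.df["z_b"].to_numpy(), truth_z)

    @given(z=st.floats(-10, 10, allow_nan=False), swap=st.booleans())
    def test_sign_flip_iff_swapped(self, z, swap):
        from pleioscan._utils import z_to_p

        p = float(z_to_p(np.array([z]))[0])
        a = _stats([("rs1", 1, 100, "G", "A", z, p, 100)])
        alleles = ("A", "G") if swap else ("G", "A")
        b = _stats([("rs1", 1, 100, *alleles, z, p, 100)])
        pair = harmonize(a, b)
        expected = -z if swap else z
        assert pair.df.loc[0, "z_b"] == pytest.approx(expected)
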