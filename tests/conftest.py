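import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pleioscan.sumstats import HarmonizedPair

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_pair(z_a, z_b=None, chrom=None, pos=None, snp=None) -> HarmonizedPair:
    """Build a HarmonizedPair directly from arrays (test helper)."""
    from pleioscan._utils import z_to_p

    z_a = np.asarray(z_a, float)
    z_b = z_a.copy() if z_b is None else np.asarray(z_b, float)
    m = len(z_a)
    df = pd.DataFrame(
        {
            "snp": snp if snp is not None else [f"rs{i}" for i in range(m)],
            "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
            "pos": pos if pos is not None else np.arange(1, m + 1) * 100_000,
            "z_a": z_a,
            "p_a": z_to_p(z_a),
            "n_a": 10_000.0,
            "z_b": z_b,
            "p_b": z_to_p(z_b),
            "n_b": 10_000.0,
        }
    )
    return HarmonizedPair(df=df)


@pytest.fixture(scope="session")
def table1_pair_stats():
    from pleioscan.datasets import table1_sumstats

    return table1_sumstats()


@pytest.fixture(scope="session")
def table1_fdr():
    from pleioscan.datasets import table1_assignment

    return table1_assignment()


@pytest.fixture(scope="session")
def table1_ld_ref():
    from pleioscan.datasets import table1_ld

    return table1_ld()


@pytest.fixture(scope="session")
def overlap_sim():
    """A small shared-architecture simulation reused across tests."""
    from pleioscan.simulate import SimulationConfig, simulate

    return simulate(SimulationConfig(m=20_000, seed=42))
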