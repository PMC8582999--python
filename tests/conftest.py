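import numpy as np
import pandas as pd
import pytest

from featde.data import CountMatrix, FeatureMap
from featde.synthetic import SimConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_cm():
    """Six features in three genes, 4 + 4 samples, hand-sized counts."""
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.poisson(50, size=(6, 8)),
        index=[f"g{g}:E{e}" for g in (1, 1, 1, 2, 2, 3) for e in [0]][:6],
        columns=[f"s{j}" for j in range(8)],
    )
    counts.index = ["g1:E1", "g1:E2", "g1:E3", "g2:E1", "g2:E2", "g3:E1"]
    groups = pd.Series(["a"] * 4 + ["b"] * 4, index=counts.columns)
    return CountMatrix(counts, groups)


@pytest.fixture
def small_fm():
    return FeatureMap(pd.Series(
        {"g1:E1": "g1", "g1:E2": "g1", "g1:E3": "g1",
         "g2:E1": "g2", "g2:E2": "g2", "g3:E1": "g3"}
    ))


@pytest.fixture(scope="session")
def sim_partial():
    """Shared moderately sized partial-regulation dataset."""
    cfg = SimConfig(n_genes=200, exons_per_gene=7, pattern="partial", seed=11)
    return simulate(cfg)
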