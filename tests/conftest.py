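import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from virotu import occurrence, simulate

settings.register_profile("suite", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def design24() -> pd.DataFrame:
    """The default 24-sample design: 4 replicates x 2 phenotypes x 3 compartments."""
    return simulate.generate_design(n_replicates=4)


@pytest.fixture(scope="session")
def default_sim(design24):
    """Default-scale simulated dataset: (params, coverage, truth)."""
    params = simulate.SimulationParams(seed=42)
    cov, truth = simulate.generate_coverage(design24, params)
    return params, cov, truth


@pytest.fixture(scope="session")
def default_occ(default_sim):
    _, cov, truth = default_sim
    occ = occurrence.call_presence(cov)
    return occ.reindex(index=truth.index, columns=truth.columns, fill_value=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def make_coverage(rows):
    """Coverage table from (votu, sample, length, covered, reads) tuples."""
    return pd.DataFrame(
        rows, columns=["votu_id", "sample_id", "contig_length", "covered_bases", "mapped_reads"]
    )
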