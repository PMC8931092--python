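import numpy as np
import pandas as pd
import pytest

from protosig import rppa, synthdata


@pytest.fixture(scope="session")
def small_config():
    return synthdata.SimConfig(
        n_patients=150, n_controls=4,
        pfg_sizes=[5, 5, 5, 6], true_k_per_pfg=[3, 3, 3, 3],
        n_signatures=3, n_constellations=3,
        centroid_separation=3.0, noise_sd=0.3,
        block_p_in=0.9, block_p_out=0.05, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """A compact cohort with clearly separated planted structure."""
    return synthdata.generate_cohort(small_config)


@pytest.fixture
def toy_matrix():
    vals = pd.DataFrame(
        [[1.0, 3.0, 2.0], [5.0, 4.0, 9.0], [0.0, 2.0, 1.0], [4.0, 4.0, 4.0]],
        index=["s1", "s2", "c1", "c2"],
        columns=["pA", "pB", "pC"])
    meta = pd.DataFrame({"is_control": [False, False, True, True],
                         "organ": ["PB", "BM", "PB", "PB"]}, index=vals.index)
    return rppa.ExpressionMatrix(vals, meta)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
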