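import numpy as np
import pandas as pd
import pytest

from gutshift import CohortConfig, generate_cohort, generate_tree
from gutshift.ml import SMALL_GRID

TINY_GRID = dict(SMALL_GRID)


@pytest.fixture(scope="session")
def small_tree():
    return generate_tree(8, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A 90-sample, 60-taxon cohort with default planted structure."""
    return generate_cohort(CohortConfig(n_per_site=(30, 30, 30), n_taxa=60, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_counts():
    """3 samples x 4 ASVs with hand-readable counts."""
    return pd.DataFrame(
        [[5, 0, 3, 2], [0, 7, 0, 1], [4, 4, 4, 4]],
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        columns=["ASV_0001", "ASV_0002", "ASV_0003", "ASV_0004"],
    )
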