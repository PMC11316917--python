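import logging

import numpy as np
import pandas as pd
import pytest

from sizestab.io_tables import CommunityTable
from sizestab.synthetic_community import SynthConfig, generate_bundle

logging.getLogger("sizestab").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def tiny_table():
    """3 samples × 4 taxa counts table with easy hand arithmetic."""
    return CommunityTable(
        pd.DataFrame(
            [[5, 5, 0, 0], [0, 10, 2, 8], [2, 1, 1, 0]],
            index=["s1", "s2", "s3"],
            columns=["t1", "t2", "t3", "t4"],
        ),
        mode="counts",
    )


@pytest.fixture
def tiny_annotation():
    return pd.DataFrame(
        {
            "domain": ["bacteria", "bacteria", "fungi", "fungi"],
            "group": ["G1", "G1", "G2", None],
            "body_size_um": [1.0, 1.0, 10.0, np.nan],
        },
        index=pd.Index(["t1", "t2", "t3", "t4"], name="taxon_id"),
    )


@pytest.fixture(scope="session")
def small_bundle():
    """Small but complete synthetic bundle shared across tests."""
    cfg = SynthConfig(n_fields=6, depth=3000, n_taxa_min=6, n_taxa_max=18, seed=42)
    return generate_bundle(cfg)
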