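import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_count_table():
    """Tiny 2+2-replicate count table with all counts positive."""
    from apicobasal.enrichment import CountTable

    counts = pd.DataFrame(
        {
            "A1": [10, 100, 40],
            "A2": [12, 110, 38],
            "B1": [9, 95, 160],
            "B2": [11, 105, 158],
        },
        index=["gene1", "gene2", "gene3"],
    )
    domains = pd.Series(
        {"A1": "apical", "A2": "apical", "B1": "basal", "B2": "basal"}
    )
    return CountTable(counts, domains)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
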