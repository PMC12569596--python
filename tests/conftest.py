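import numpy as np
import pandas as pd
import pytest

from adict.conservation import compute_conservation_scores, relative_conservation


@pytest.fixture
def divergence_table():
    """Six genes covering retained and every exclusion branch."""
    return pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC", "gD", "gE", "gF"],
            "dN": [0.05, 0.08, 0.0, 0.02, 0.01, 0.03],
            "dS": [0.10, 0.10, 0.10, 0.0, 0.10, 0.10],
            "is_one2one": [True, True, True, True, False, True],
            "has_paralog": [False, False, False, False, False, True],
        }
    )


@pytest.fixture
def scored_genes():
    """A 12-gene conservation table with RCS centred on 4 constant genes."""
    rng = np.random.default_rng(42)
    n = 12
    omega = rng.uniform(0.05, 0.7, size=n)
    div = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "dN": omega * 0.1,
            "dS": 0.1,
            "is_one2one": True,
            "has_paralog": False,
        }
    )
    cons = compute_conservation_scores(div)
    return relative_conservation(cons, {f"g{i}" for i in range(4)})


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
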