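import numpy as np
import pandas as pd
import pytest

import phylofa as pf


@pytest.fixture
def three_tip():
    """Ultrametric 3-tip tree of height 2: ((A:1,B:1):1,C:2);"""
    return pf.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    """Equal-depth star: identity-proportional covariance, K = 1 exactly."""
    return pf.parse_newick("(A:1,B:1,C:1,D:1,E:1);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table():
    """Ten measurements, two species, four FAs (% of total)."""
    rows = []
    rng = np.random.default_rng(7)
    for i in range(10):
        sp = "Alpha one" if i < 5 else "Beta two"
        base = np.array([50.0, 30.0, 15.0, 5.0]) + rng.normal(0, 1, 4)
        base = 100 * base / base.sum()
        rows.append(
            {
                "sample_id": f"s{i}",
                "species": sp,
                "site": "X",
                "habitat": "forest",
                "16:0": base[0],
                "18:1w9": base[1],
                "18:2w6,9": base[2],
                "20:5w3": base[3],
            }
        )
    return pd.DataFrame(rows)
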