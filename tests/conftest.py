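import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20150494)


@pytest.fixture
def four_taxon_tree():
    """((TSA,(LOC,MCR)),MCA) with consistent node ages."""
    from karyorate.homology import parse_newick_dated

    return parse_newick_dated(
        "((TSA,(LOC,MCR)N2)N1,MCA)R;",
        {"N2": (10.0, 1.0), "N1": (18.0, 2.0), "R": (30.0, 3.0)},
    )
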