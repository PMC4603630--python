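import numpy as np
import pytest

from adjevo.trees import parse_species_tree


@pytest.fixture()
def species4():
    """Four extant species, fully resolved, with branch lengths."""
    return parse_species_tree(
        "(((A:0.2,B:0.3)X:0.1,C:0.4)Y:0.2,D:0.5)R;")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
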