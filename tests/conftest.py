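import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mulrecon.simulate import make_reference_fixture
from mulrecon.treeio import parse_newick

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def gene_tree(nwk: str):
    """Parse a gene tree whose leaf labels are lowercase species letters plus
    an optional copy digit: 'a1' -> species 'A', gene id 'a1'."""
    t = parse_newick(nwk)
    for leaf in t.leaves():
        leaf.species = leaf.label.rstrip("0123456789").upper()
        leaf.gene_id = leaf.label
    return t


@pytest.fixture(scope="session")
def reference():
    """The 8-taxon study fixture: (tree, species map)."""
    return make_reference_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
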