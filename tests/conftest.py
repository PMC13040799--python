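import pytest

from mgpm.fixtures import random_mixed_instance as random_instance  # noqa: F401
from mgpm.models import ModelSpec
from mgpm.treeio import random_clade_painting, random_ultrametric_tree, read_newick


@pytest.fixture
def three_tip_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def yule10():
    return random_ultrametric_tree(10, 7)


@pytest.fixture
def two_regime_spec(yule10):
    painting = random_clade_painting(yule10, 2, 3)
    return ModelSpec(yule10, painting, ("OU", "BM"))

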