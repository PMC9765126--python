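import dendropy
import pytest

from cazytrait import default_activity_map
from cazytrait.conservation import TreeIndex
from cazytrait.io_formats import GenomeMetadata


def tree_from_newick(newick: str) -> dendropy.Tree:
    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    t.is_rooted = True
    return t


@pytest.fixture(scope="session")
def amap():
    return default_activity_map()


@pytest.fixture()
def balanced4():
    """Unit balanced 4-tip tree: root depth 2, cherries (A,B) and (C,D)."""
    return tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture()
def balanced4_index(balanced4):
    return TreeIndex(balanced4)


@pytest.fixture()
def tiny_metadata():
    return [
        GenomeMetadata("MAG1", "PhylumA", "soil", "high", 1),
        GenomeMetadata("MAG2", "PhylumA", "soil", "high", 1),
        GenomeMetadata("MAG3", "PhylumB", "marine", "high", 0),
    ]
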