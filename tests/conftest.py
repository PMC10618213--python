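import logging

import pytest

from canapy.grid import GridCell, build_grid, filter_min_richness
from canapy.phylo import prune_to_shared, read_newick
from canapy.synthetic import ScenarioSpec, generate_scenario

logging.disable(logging.WARNING)


@pytest.fixture
def cherry_tree():
    """Two-species cherry, both branches length 1."""
    return read_newick("(A:1,B:1);")


@pytest.fixture
def cherry_grid():
    """A in c1 only; B in c1 and c2."""
    cells = [GridCell("c1", 0, 0), GridCell("c2", 1, 0)]
    return build_grid([("A", "c1"), ("B", "c1"), ("B", "c2")], cells)


@pytest.fixture(scope="session")
def demo_scenario():
    """The default synthetic scenario at seed 0 (shared, read-only)."""
    return generate_scenario(ScenarioSpec(seed=0))


@pytest.fixture(scope="session")
def demo_analysis(demo_scenario):
    """(tree, filtered grid) for the demo scenario."""
    grid = filter_min_richness(demo_scenario.grid, 5)
    return prune_to_shared(demo_scenario.tree, grid)
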