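import numpy as np
import pytest

from astromorph.morphology_io import CellMorphology
from astromorph.synthetic_data import MorphClassSpec, generate_astrocyte

# small-arbor spec used wherever an O(n^3)-or-worse oracle must stay cheap
SMALL_SPEC = MorphClassSpec("small", n_primary=3, branch_prob=0.5, max_order=3,
                            segment_length=(22.0, 6.0), step=11.0, wiggle=0.25)


@pytest.fixture(scope="session")
def small_cells():
    """50 random small synthetic arbors (tens of nodes each)."""
    return [generate_astrocyte(SMALL_SPEC, seed=1000 + i, cell_id=f"c{i:03d}")
            for i in range(50)]


def make_cell(nodes, cell_id="cell"):
    """Build a CellMorphology from (id, parent, x, y, z, radius) tuples."""
    arr = np.array(nodes, dtype=float)
    return CellMorphology(cell_id,
                          ids=arr[:, 0].astype(int),
                          parents=arr[:, 1].astype(int),
                          xyz=arr[:, 2:5],
                          radius=arr[:, 5],
                          type_tag=np.full(len(arr), 7))


def straight_cable(n_nodes=11, length=100.0, radius=1.0):
    """Unbranched cable along +x: soma at origin plus n_nodes-1 children."""
    nodes = [(1, -1, 0, 0, 0, radius)]
    for i in range(1, n_nodes):
        nodes.append((i + 1, i, length * i / (n_nodes - 1), 0, 0, radius))
    return make_cell(nodes)
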