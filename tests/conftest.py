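import numpy as np
import pytest

from gliamorph.grid import VoxelGrid
from gliamorph.synth import GliaModel, SpotModel, grow_glia, render_scene


@pytest.fixture(scope="session")
def small_grid():
    return VoxelGrid(shape=(64, 64, 64), voxel_size=(0.3, 0.3, 0.3))


@pytest.fixture(scope="session")
def rendered_scene(small_grid):
    """One cell + spots rendered at low noise; shared across tests."""
    center = tuple(e / 2 for e in small_grid.physical_extent)
    cell = grow_glia(GliaModel(soma_center=center, mean_segment=3.0), 11)
    stack, gt = render_scene(
        [cell],
        SpotModel(density_per_um3=0.004, frac_contact=0.1, frac_engulfed=0.1),
        small_grid,
        seed=42,
    )
    return stack, gt


def random_tree(rng, n_edges=50, scale=10.0):
    """Random spatial tree rooted at the origin (for geometry oracles)."""
    from gliamorph.morphometry import SkeletonGraph

    positions = [np.zeros(3)]
    edges = []
    for _ in range(n_edges):
        parent = int(rng.integers(len(positions)))
        positions.append(positions[parent] + rng.normal(scale=scale / 4, size=3))
        edges.append((parent, len(positions) - 1))
    return SkeletonGraph(positions=np.array(positions), edges=np.array(edges), root=0)
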