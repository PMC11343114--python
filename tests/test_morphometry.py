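import numpy as np
import pytest

from gliamorph.grid import ROI, VoxelGrid
from gliamorph.morphometry import (
    CellMask,
    SkeletonGraph,
    cell_density,
    cell_volume,
    segment_cells,
    sholl_profile,
    skeletonize_cell,
    territory_volume,
    total_process_length,
    write_swc,
)
from gliamorph.reference import hull_volume_facet_enumeration, sholl_counts_sampled

from conftest import random_tree


def tube_mask(grid, a, b, radius):
    """Capsule (cylinder with round caps) between physical points a, b."""
    idx = np.indices(grid.shape)
    p = (np.stack(idx, -1) + 0.5) * np.asarray(grid.voxel_size)
    a, b = np.asarray(a, float), np.asarray(b, float)
    ab = b - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0, 1)
    d = np.linalg.norm(p - (a + t[..., None] * ab), axis=-1)
    return d <= radius


class TestProcessLength:
    def test_pythagorean_edge(self):
        s = SkeletonGraph(positions=[[0, 0, 0], [0, 3, 4]], edges=[[0, 1]])
        assert total_process_length(s) == pytest.approx(5.0)

    def test_empty_edges(self):
        s = SkeletonGraph(positions=[[0, 0, 0]], edges=np.empty((0, 2)))
        assert total_process_length(s) == 0.0

    def test_random_tree_equals_bruteforce_sum(self):
        s = random_tree(np.random.default_rng(3), n_edges=50)
        manual = sum(
            float(np.linalg.norm(s.positions[a] - s.positions[b])) for a, b in s.edges
        )
        assert total_process_length(s) == pytest.approx(manual)

    def test_adding_edge_never_decreases_length(self):
        s = random_tree(np.random.default_rng(4), n_edges=20)
        before = total_process_length(s)
        grown = SkeletonGraph(
            positions=np.vstack([s.positions, [[30, 0, 0]]]),
            edges=np.vstack([s.edges, [[0, s.n_nodes]]]),
        )
        assert total_process_length(grown) >= before


class TestSholl:
    def test_single_straight_process(self):
        s = SkeletonGraph(positions=[[0, 0, 0], [0, 0, 20]], edges=[[0, 1]])
        p = sholl_profile(s, radii=np.array([5, 10, 15, 25], float))
        assert p.counts.tolist() == [1, 1, 1, 0]
        assert p.complexity == 3

    def test_trunk_with_two_branches(self):
        s = SkeletonGraph(
            positions=[[0, 0, 0], [0, 0, 10], [0, 5, 18], [0, -5, 18]],
            edges=[[0, 1], [1, 2], [1, 3]],
        )
        p = sholl_profile(s, radii=np.array([5.0, 15.0]))
        assert p.counts.tolist() == [1, 2]

    def test_radius_beyond_tree_counts_zero(self):
        s = random_tree(np.random.default_rng(0), n_edges=10)
        rmax = s.root_distances().max()
        p = sholl_profile(s, radii=np.array([2 * rmax + 1]))
        assert p.counts.tolist() == [0]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_sampling_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = random_tree(rng, n_edges=40)
        radii = np.sort(rng.uniform(0.5, 1.2 * s.root_distances().max(), size=30))
        p = sholl_profile(s, radii=radii)
        oracle = sholl_counts_sampled(s.positions, s.edges, s.root, radii)
        np.testing.assert_array_equal(p.counts, oracle)

    def test_no_radii_is_error(self):
        s = random_tree(np.random.default_rng(0), n_edges=5)
        with pytest.raises(ValueError):
            sholl_profile(s, radii=np.array([]))


class TestTerritory:
    def test_cube_volume(self):
        pts = np.array([[z, y, x] for z in (0, 10) for y in (0, 10) for x in (0, 10)], float)
        assert territory_volume(pts) == pytest.approx(1000.0)

    def test_tetrahedron_volume(self):
        pts = np.array([[0, 0, 0], [6, 0, 0], [0, 6, 0], [0, 0, 6]], float)
        assert territory_volume(pts) == pytest.approx(36.0)

    def test_degenerate_coplanar_is_error(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        with pytest.raises(ValueError, match="degenerate"):
            territory_volume(pts)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_facet_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(scale=8.0, size=(30, 3))
        assert territory_volume(pts) == pytest.approx(
            hull_volume_facet_enumeration(pts), rel=1e-7)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(50, 3))
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(rng=7).as_matrix()
        assert territory_volume(pts @ rot.T) == pytest.approx(
            territory_volume(pts), rel=1e-6)


class TestVolumesDensity:
    def test_voxel_count_volume(self):
        g = VoxelGrid((10, 10, 10), (0.1, 0.1, 0.1))
        m = np.zeros(g.shape, bool)
        m.ravel()[:1000] = True
        cell = CellMask(m, soma_um=np.array([0.05, 0.05, 0.05]))
        assert cell_volume(cell, g) == pytest.approx(1.0)

    def test_empty_mask_error(self):
        g = VoxelGrid((4, 4, 4), (0.1, 0.1, 0.1))
        with pytest.raises(ValueError):
            cell_volume(CellMask(np.zeros(g.shape, bool), soma_um=np.zeros(3)), g)

    def test_digitized_ball_near_analytic(self):
        g = VoxelGrid((80, 80, 80), (0.1, 0.1, 0.1))
        c = (40 + 0.5) * 0.1
        idx = np.indices(g.shape)
        p = (np.stack(idx, -1) + 0.5) * 0.1
        ball = np.linalg.norm(p - c, axis=-1) <= 3.0
        cell = CellMask(ball, soma_um=np.full(3, c))
        assert cell_volume(cell, g) == pytest.approx(36 * np.pi, rel=0.05)

    def test_density_counts_somata_inside_roi(self):
        g = VoxelGrid((100, 100, 100), (1.0, 1.0, 1.0))
        roi = ROI.full(g)  # 10^6 um^3
        cells = [CellMask(np.ones(g.shape, bool), soma_um=np.array([50.0, 50, 50]),
                          cell_id=i) for i in range(5)]
        count, dens = cell_density(cells, roi, g)
        assert (count, dens) == (5, pytest.approx(5.0))
        outside = CellMask(np.ones(g.shape, bool), soma_um=np.array([150.0, 50, 50]))
        count, _ = cell_density(cells + [outside], roi, g)
        assert count == 5

    def test_zero_cells(self):
        g = VoxelGrid((10, 10, 10), (1.0, 1.0, 1.0))
        count, dens = cell_density([], ROI.full(g), g)
        assert count == 0 and dens == 0.0


class TestSkeletonize:
    def test_straight_tube_length(self):
        g = VoxelGrid((120, 24, 24), (0.25, 0.25, 0.25))
        c = (11 + 0.5) * 0.25
        m = tube_mask(g, (5, c, c), (25, c, c), 0.5)
        sk = skeletonize_cell(CellMask(m, soma_um=np.array([5.0, c, c])), g)
        assert sk.total_length() == pytest.approx(20.0, rel=0.10)
        assert sk.is_tree()

    def test_soma_only_ball_collapses(self):
        g = VoxelGrid((30, 30, 30), (0.25, 0.25, 0.25))
        c = (15 + 0.5) * 0.25
        idx = np.indices(g.shape)
        p = (np.stack(idx, -1) + 0.5) * 0.25
        ball = np.linalg.norm(p - c, axis=-1) <= 2.0
        sk = skeletonize_cell(CellMask(ball, soma_um=np.full(3, c)), g)
        assert sk.total_length() < 2.0  # degenerate, near-point

    def test_y_shape_single_branch_node(self):
        g = VoxelGrid((80, 80, 41), (0.25, 0.25, 0.25))
        zc = (20 + 0.5) * 0.25
        m = (tube_mask(g, (2, 10.125, zc), (10, 10.125, zc), 0.5)
             | tube_mask(g, (10, 10.125, zc), (16, 5, zc), 0.5)
             | tube_mask(g, (10, 10.125, zc), (16, 15, zc), 0.5))
        sk = skeletonize_cell(CellMask(m, soma_um=np.array([2.0, 10.125, zc])), g)
        assert sk.n_branch_points() == 1
        assert sk.is_tree()

    def test_tiny_mask_is_error(self):
        g = VoxelGrid((8, 8, 8), (0.25, 0.25, 0.25))
        m = np.zeros(g.shape, bool)
        m[4, 4, 4] = True
        with pytest.raises(ValueError):
            skeletonize_cell(CellMask(m, soma_um=np.ones(3)), g)

    def test_anisotropic_voxels_give_physical_lengths(self):
        # same physical tube sampled anisotropically (dz = 2 dy)
        g = VoxelGrid((60, 24, 24), (0.5, 0.25, 0.25))
        c = (11 + 0.5) * 0.25
        m = tube_mask(g, (5, c, c), (25, c, c), 0.5)
        sk = skeletonize_cell(CellMask(m, soma_um=np.array([5.0, c, c])), g)
        assert sk.total_length() == pytest.approx(20.0, rel=0.12)

    def test_swc_export_round_numbers(self, tmp_path):
        s = SkeletonGraph(positions=[[0, 0, 0], [0, 0, 5], [0, 3, 9]],
                          edges=[[0, 1], [1, 2]])
        p = tmp_path / "cell.swc"
        write_swc(s, p)
        lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 3
        assert lines[0].split()[1] == "1"  # root is soma type
        assert lines[0].split()[-1] == "-1"


class TestSegmentation:
    def test_three_separated_cells_recovered(self, small_grid):
        from gliamorph.synth import GliaModel, grow_glia, render_scene

        e = small_grid.physical_extent
        centers = [(e[0] / 2, e[1] / 4, e[2] / 4),
                   (e[0] / 2, 3 * e[1] / 4, e[2] / 4),
                   (e[0] / 2, e[1] / 2, 3 * e[2] / 4)]
        cells = [grow_glia(GliaModel(soma_center=c, mean_segment=1.5, n_primary=3,
                                     max_depth=1), s) for s, c in enumerate(centers)]
        stack, gt = render_scene(cells, None, small_grid, seed=5)
        found = segment_cells(stack.channel("iba1"), small_grid, min_volume_um3=20.0)
        assert len(found) == 3
        # match each found cell to its ground-truth mask by best Dice
        for f in found:
            dices = [2 * (f.mask & t.mask).sum() / (f.mask.sum() + t.mask.sum())
                     for t in gt.masks]
            assert max(dices) > 0.7

    def test_flat_channel_yields_no_cells(self, small_grid):
        assert segment_cells(np.zeros(small_grid.shape), small_grid) == []

    def test_min_volume_filter(self, small_grid):
        ch = np.zeros(small_grid.shape, np.float32)
        ch[30:32, 30:32, 30:32] = 100.0  # 8 voxels = 0.216 um^3
        assert segment_cells(ch, small_grid, threshold=50.0,
                             smooth_sigma_um=0, background_sigma_um=0,
                             min_volume_um3=50.0) == []

    def test_empty_roi_is_error(self, small_grid):
        with pytest.raises(ValueError, match="empty ROI"):
            segment_cells(np.zeros(small_grid.shape), small_grid,
                          roi=ROI(mask=np.zeros(small_grid.shape, bool)))
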