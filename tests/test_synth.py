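import numpy as np
import pytest

from gliamorph.grid import VoxelGrid
from gliamorph.synth import (
    CohortSpec,
    GliaModel,
    NoiseModel,
    SpotModel,
    generate_cohort,
    grow_glia,
    rasterize_cell,
    render_scene,
    simulate_animal_lengths,
    two_group_spec,
)


class TestGrowth:
    def test_unbranched_single_process(self):
        m = GliaModel(n_primary=1, branch_prob=0.0, mean_segment=20.0,
                      segment_cv=0.0, max_depth=1)
        cell = grow_glia(m, 0)
        assert cell.true_length == pytest.approx(20.0)
        assert cell.n_branch_points == 0
        # skeleton additionally carries the soma-center-to-surface connector
        assert cell.skeleton.total_length() == pytest.approx(20.0 + m.soma_radius)

    def test_determinism(self):
        m = GliaModel()
        a, b = grow_glia(m, 123), grow_glia(m, 123)
        np.testing.assert_array_equal(a.skeleton.positions, b.skeleton.positions)
        assert a.true_length == b.true_length

    def test_different_seeds_differ(self):
        m = GliaModel()
        assert grow_glia(m, 1).true_length != grow_glia(m, 2).true_length

    def test_branch_count_matches_branching_law_expectation(self):
        # binary branching w.p. p at each segment end while depth < max:
        # E[branches] follows the recursion B(d) = p(1 + 2 B(d+1))
        m = GliaModel(n_primary=2, branch_prob=0.5, max_depth=3, tortuosity=0.0)
        expected = m.expected_branch_count()
        counts = np.array([grow_glia(m, s).n_branch_points for s in range(500)])
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_total_length_matches_expectation(self):
        m = GliaModel(branch_prob=0.6, max_depth=2, segment_cv=0.3)
        expected = m.expected_total_length()
        lengths = np.array([grow_glia(m, s).true_length for s in range(400)])
        se = lengths.std(ddof=1) / np.sqrt(len(lengths))
        assert abs(lengths.mean() - expected) < 3 * se

    def test_zero_primaries_is_error(self):
        with pytest.raises(ValueError):
            GliaModel(n_primary=0, max_depth=2)

    def test_rasterized_mask_covers_skeleton(self):
        g = VoxelGrid((64, 64, 64), (0.3, 0.3, 0.3))
        cell = grow_glia(GliaModel(soma_center=(9.6, 9.6, 9.6), mean_segment=3.0), 5)
        mask, clipped = rasterize_cell(cell, g)
        assert clipped == 0.0
        idx = np.floor(cell.skeleton.positions / 0.3).astype(int)
        assert mask.mask[tuple(idx.T)].all()


class TestRender:
    def test_empty_scene_is_zero_without_noise(self):
        g = VoxelGrid((32, 32, 32), (0.3, 0.3, 0.3))
        stack, gt = render_scene([], None, g, noise=NoiseModel(read_sd=0, photon_scale=None))
        assert np.all(stack.channel("iba1") == 0)
        assert np.all(stack.channel("agrp") == 0)
        assert len(gt.spots) == 0

    def test_single_spot_peak_at_voxel(self):
        g = VoxelGrid((32, 32, 32), (0.3, 0.3, 0.3))
        sm = SpotModel(density_per_um3=1.0 / np.prod(g.physical_extent),
                       frac_contact=0, frac_engulfed=0, free_min_distance=0)
        stack, gt = render_scene([], sm, g, noise=NoiseModel(read_sd=0, photon_scale=None),
                                 seed=4)
        assert len(gt.spots) == 1
        peak = np.unravel_index(np.argmax(stack.channel("agrp")), g.shape)
        truth_idx = np.floor(gt.spots[["z", "y", "x"]].to_numpy()[0] / 0.3)
        np.testing.assert_array_equal(peak, truth_idx)

    def test_planted_engulfed_fraction_exact_in_ground_truth(self):
        g = VoxelGrid((80, 80, 80), (0.3, 0.3, 0.3))
        center = tuple(e / 2 for e in g.physical_extent)
        cell = grow_glia(GliaModel(soma_center=center), 7)
        sm = SpotModel(density_per_um3=0.002, frac_contact=0.2, frac_engulfed=0.3)
        _, gt = render_scene([cell], sm, g, seed=8)
        planted = gt.spots["planted"].to_numpy()
        truth = gt.spots["class"].to_numpy()
        # classes recomputed by the shared rule agree with the planting law
        np.testing.assert_array_equal(planted, truth)
        n = len(gt.spots)
        assert gt.engulfed_fraction == pytest.approx(
            (planted == "engulfed").sum() / n)

    def test_noise_level_does_not_change_ground_truth(self):
        g = VoxelGrid((48, 48, 48), (0.3, 0.3, 0.3))
        center = tuple(e / 2 for e in g.physical_extent)
        cell = grow_glia(GliaModel(soma_center=center, mean_segment=2.0), 3)
        _, gt1 = render_scene([cell], SpotModel(), g, noise=NoiseModel(read_sd=1), seed=9)
        _, gt2 = render_scene([cell], SpotModel(), g, noise=NoiseModel(read_sd=20), seed=9)
        np.testing.assert_array_equal(gt1.spots[["z", "y", "x"]].to_numpy(),
                                      gt2.spots[["z", "y", "x"]].to_numpy())
        np.testing.assert_array_equal(gt1.spots["class"], gt2.spots["class"])

    def test_nonpositive_psf_is_error(self):
        g = VoxelGrid((16, 16, 16), (0.3, 0.3, 0.3))
        with pytest.raises(ValueError):
            render_scene([], None, g, psf_sigma_um=(0, 0.2, 0.2))


class TestCohort:
    def test_counts_and_metadata(self):
        spec = CohortSpec(animals_per_group=4, shape=(40, 40, 40), master_seed=3)
        data = generate_cohort(spec)
        assert len(data.stacks) == 8
        assert len(data.ground_truths) == 8
        groups = {s.metadata["group"] for s in data.stacks}
        assert groups == {"NCD", "MHFD"}

    def test_reproducible_in_memory(self):
        spec = CohortSpec(animals_per_group=2, shape=(40, 40, 40), master_seed=5)
        d1, d2 = generate_cohort(spec), generate_cohort(spec)
        for s1, s2 in zip(d1.stacks, d2.stacks):
            np.testing.assert_array_equal(s1.channel("iba1"), s2.channel("iba1"))
        assert d1.index.equals(d2.index)

    def test_written_cohort_byte_identical(self, tmp_path):
        spec = CohortSpec(animals_per_group=2, shape=(32, 32, 32), master_seed=7)
        hashes = []
        import hashlib

        for rep in ("r1", "r2"):
            d = tmp_path / rep
            generate_cohort(spec, out_dir=d)
            m = hashlib.sha256()
            for f in sorted(d.iterdir()):
                m.update(f.read_bytes())
            hashes.append(m.hexdigest())
        assert hashes[0] == hashes[1]

    def test_planted_length_ratio_in_ground_truth(self):
        # generator-level: planted 87% increase recovered from true lengths
        base, alt = GliaModel(), GliaModel(mean_segment=4.0 * 1.87)
        a = simulate_animal_lengths(base, 20, 11)
        b = simulate_animal_lengths(alt, 20, 12)
        assert b.mean() / a.mean() == pytest.approx(1.87, rel=0.15)

    def test_fewer_than_two_animals_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(animals_per_group=1)

    def test_two_group_spec_plants_overrides(self):
        spec = two_group_spec(length_ratio=1.5, density_ratio=2.0, animals_per_group=2)
        glia, spots = spec.group_models("MHFD")
        glia0, spots0 = spec.group_models("NCD")
        assert glia.mean_segment == pytest.approx(1.5 * glia0.mean_segment)
        assert spots.density_per_um3 == pytest.approx(2.0 * spots0.density_per_um3)
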