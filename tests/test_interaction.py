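import numpy as np
import pandas as pd
import pytest

from gliamorph.grid import ROI, VoxelGrid
from gliamorph.interaction import (
    SignedDistanceField,
    cd68_volume,
    classify_point_distances,
    classify_spots,
    engulfment_summary,
    signed_distance,
)
from gliamorph.morphometry import CellMask
from gliamorph.reference import signed_distance_boundary_search


def ball_mask(grid, center_um, radius):
    idx = np.indices(grid.shape)
    p = (np.stack(idx, -1) + 0.5) * np.asarray(grid.voxel_size)
    return np.linalg.norm(p - np.asarray(center_um), axis=-1) <= radius


class TestSignedDistance:
    def test_ball_inside_outside(self):
        g = VoxelGrid((64, 64, 64), (0.25, 0.25, 0.25))
        c = np.full(3, 8.0)
        cell = CellMask(ball_mask(g, c, 5.0), soma_um=c, cell_id=1)
        f = signed_distance([cell], g)
        half_diag = np.linalg.norm(g.voxel_size) / 2
        outside = f.distance_at(c + [0, 0, 6.0])[0]
        inside = f.distance_at(c + [0, 0, 4.0])[0]
        assert outside == pytest.approx(1.0, abs=half_diag)
        assert inside == pytest.approx(-1.0, abs=half_diag)

    def test_no_masks_is_error(self):
        g = VoxelGrid((8, 8, 8), (0.25, 0.25, 0.25))
        with pytest.raises(ValueError):
            signed_distance([], g)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_boundary_search_oracle(self, seed):
        g = VoxelGrid((24, 24, 24), (0.4, 0.3, 0.3))
        rng = np.random.default_rng(seed)
        mask = np.zeros(g.shape, bool)
        for _ in range(3):
            c = rng.uniform(2, 6, size=3)
            mask |= ball_mask(g, c, rng.uniform(1.0, 2.0))
        f = signed_distance([CellMask(mask, soma_um=np.full(3, 3.0), cell_id=1)], g)
        oracle = signed_distance_boundary_search(mask, g.voxel_size)
        half_diag = np.linalg.norm(g.voxel_size) / 2
        assert np.max(np.abs(f.field - oracle)) <= half_diag + 1e-6

    def test_nearest_cell_labels(self):
        g = VoxelGrid((32, 32, 32), (0.3, 0.3, 0.3))
        c1, c2 = np.array([4.8, 4.8, 2.4]), np.array([4.8, 4.8, 7.2])
        cells = [CellMask(ball_mask(g, c1, 1.0), soma_um=c1, cell_id=1),
                 CellMask(ball_mask(g, c2, 1.0), soma_um=c2, cell_id=2)]
        f = signed_distance(cells, g)
        assert f.nearest_cell_at(c1 + [0, 0, 0.5])[0] == 1
        assert f.nearest_cell_at(c2 - [0, 0, 0.5])[0] == 2


class TestClassification:
    @pytest.mark.parametrize("d,expected_shell,expected_full", [
        (0.9, "contact", "contact"),
        (-0.3, "engulfed", "engulfed"),
        (2.0, "free", "free"),
        (-0.8, "contact", "engulfed"),  # deep interior: shell rule excludes
        (0.0, "engulfed", "engulfed"),
        (1.0, "contact", "contact"),
    ])
    def test_distance_rules(self, d, expected_shell, expected_full):
        cls_s, deep_s = classify_point_distances(np.array([d]), mode="shell")
        cls_f, _ = classify_point_distances(np.array([d]), mode="full_interior")
        assert cls_s[0] == expected_shell
        assert cls_f[0] == expected_full
        assert bool(deep_s[0]) == (d <= -0.5)

    def test_nan_distance_is_error(self):
        with pytest.raises(ValueError):
            classify_point_distances(np.array([np.nan]))

    def test_every_spot_gets_exactly_one_class(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(-3, 3, size=500)
        for mode in ("shell", "full_interior"):
            cls, _ = classify_point_distances(d, mode=mode)
            assert set(np.unique(cls)) <= {"free", "contact", "engulfed"}
            assert len(cls) == 500

    def test_contact_count_monotone_in_contact_max(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(-3, 3, size=500)
        prev = -1
        for cmax in [0.2, 0.5, 1.0, 2.0, 3.0]:
            cls, _ = classify_point_distances(d, contact_max=cmax)
            n = int(np.sum(cls != "free"))
            assert n >= prev
            prev = n

    def test_matches_ground_truth_on_true_centroids(self):
        from gliamorph.benchmark import classifier_agreement

        r = classifier_agreement(n_scenes=5, seed=2)
        assert r["n_spots"] > 0
        assert r["n_agree"] == r["n_spots"]


class TestCD68:
    def _setup(self):
        g = VoxelGrid((48, 48, 48), (0.25, 0.25, 0.25))
        c = np.full(3, 6.0)
        cell = CellMask(ball_mask(g, c, 3.0), soma_um=c, cell_id=1)
        return g, cell

    def test_zero_channel_zero_volume(self):
        g, cell = self._setup()
        df = cd68_volume(np.zeros(g.shape), [cell], g)
        assert df["cd68_volume_um3"].tolist() == [0.0]

    def test_planted_puncta_recovered_noiseless(self):
        g, cell = self._setup()
        rng = np.random.default_rng(0)
        inside = np.argwhere(cell.mask)
        pick = inside[rng.choice(len(inside), size=200, replace=False)]
        ch = np.zeros(g.shape, np.float32)
        ch[tuple(pick.T)] = 80.0
        planted = 200 * g.voxel_volume
        df = cd68_volume(ch, [cell], g)
        assert df["cd68_volume_um3"].sum() == pytest.approx(planted, rel=0.10)

    def test_puncta_outside_masks_ignored(self):
        g, cell = self._setup()
        ch = np.zeros(g.shape, np.float32)
        ch[0:4, 0:4, 0:4] = 90.0  # far from the cell
        ch[tuple(np.argwhere(cell.mask)[:20].T)] = 90.0
        df = cd68_volume(ch, [cell], g)
        assert df["cd68_volume_um3"].sum() <= 25 * g.voxel_volume

    def test_cd68_never_exceeds_cell_volume(self):
        g, cell = self._setup()
        ch = np.full(g.shape, 0.0, np.float32)
        ch[cell.mask] = 100.0
        ch[~cell.mask] = 1.0
        df = cd68_volume(ch, [cell], g)
        assert (df["cd68_volume_um3"] <= df["cell_volume_um3"] + 1e-9).all()

    def test_no_cells_is_error(self):
        g, _ = self._setup()
        with pytest.raises(ValueError):
            cd68_volume(np.zeros(g.shape), [], g)


class TestEngulfmentSummary:
    def test_fraction(self):
        g = VoxelGrid((10, 10, 10), (1.0, 1.0, 1.0))
        rec = pd.DataFrame({"class": ["engulfed"] * 4 + ["free"] * 36})
        s = engulfment_summary(rec, ROI.full(g), g)
        assert s["engulfed_fraction"] == pytest.approx(0.10)
        assert s["n_engulfed"] == 4
        assert s["engulfed_density_per_1e3um3"] == pytest.approx(4.0)

    def test_zero_spots_missing_with_warning(self):
        g = VoxelGrid((10, 10, 10), (1.0, 1.0, 1.0))
        with pytest.warns(UserWarning):
            s = engulfment_summary(pd.DataFrame({"class": []}), ROI.full(g), g)
        assert np.isnan(s["engulfed_fraction"])
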