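"""Synthetic two-channel confocal stacks with full ground truth.

The generator grows branching glial cells as stochastic trees (binary
branching at gamma-distributed arc-length intervals, persistent-random-
walk tortuosity), rasterises them as tubes around the skeleton plus a
soma ball, plants fixed-diameter terminal "spots" at controlled signed
distances from the cell surface (free / contact / engulfed), renders both
channels through a separable Gaussian PSF with Poisson photon noise and
Gaussian read noise, and records ground truth for every object.

Ground-truth interaction classes are assigned by the *same* distance rule
as the measurement pipeline (:func:`gliamorph.interaction.classify_point_distances`),
so the classifier can be validated against them with zero disagreement.

Everything is deterministic under a fixed seed; per-animal streams are
derived as ``default_rng([master_seed, group_index, animal_index, ...])``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import VoxelGrid
from .interaction import classify_point_distances, signed_distance
from .morphometry import CellMask, SkeletonGraph
from .stack import MultiChannelStack, write_stack

__all__ = [
    "GliaModel",
    "SpotModel",
    "CD68Model",
    "NoiseModel",
    "CohortSpec",
    "GrownCell",
    "SceneGroundTruth",
    "grow_glia",
    "rasterize_cell",
    "render_scene",
    "generate_cohort",
    "simulate_animal_lengths",
    "two_group_spec",
]


# ---------------------------------------------------------------------------
# models


@dataclass(frozen=True)
class GliaModel:
    """Parameters of a procedurally grown ramified glial cell.

    Lengths in µm.  ``branch_prob`` is the probability that a process
    branches into two daughters at the end of each arc-length interval
    (while the branch depth is below ``max_depth``); intervals are
    gamma-distributed with mean ``mean_segment`` and coefficient of
    variation ``segment_cv``.  ``tortuosity`` is the sd of the per-step
    direction perturbation of the persistent random walk.
    """

    soma_center: tuple[float, float, float] | None = None
    soma_radius: float = 2.0
    n_primary: int = 4
    branch_prob: float = 0.8
    mean_segment: float = 4.0
    segment_cv: float = 0.25
    process_radius: float = 0.5
    max_depth: int = 2
    tortuosity: float = 0.15
    step: float = 0.5
    intensity: float = 100.0

    def __post_init__(self) -> None:
        if self.soma_radius <= 0 or self.process_radius <= 0:
            raise ValueError("radii must be > 0")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch probability must be in [0, 1]")
        if self.max_depth >= 1 and self.n_primary < 1:
            raise ValueError("zero primary processes with branch depth > 0")
        if self.mean_segment <= 0 or self.step <= 0:
            raise ValueError("segment length and step must be > 0")
        if self.segment_cv < 0:
            raise ValueError("segment dispersion must be >= 0")

    # closed-form branching-process expectations (oracle for simulations)
    def expected_segments_per_primary(self) -> float:
        s = 1.0
        for _ in range(self.max_depth - 1):
            s = 1.0 + 2.0 * self.branch_prob * s
        return s

    def expected_branch_count(self) -> float:
        b = 0.0
        for _ in range(self.max_depth - 1):
            b = self.branch_prob * (1.0 + 2.0 * b)
        return self.n_primary * b

    def expected_total_length(self) -> float:
        return self.n_primary * self.mean_segment * self.expected_segments_per_primary()


@dataclass(frozen=True)
class SpotModel:
    """Placement law and appearance of punctate terminals.

    ``frac_contact`` of spots are planted within the contact shell of a
    cell surface, ``frac_engulfed`` just inside it; the remainder are
    free, at least ``free_min_distance`` outside any cell.
    """

    diameter: float = 0.8
    intensity: float = 100.0
    density_per_um3: float = 0.003
    frac_contact: float = 0.05
    frac_engulfed: float = 0.05
    min_separation: float = 1.6
    border_margin: float = 1.5
    free_min_distance: float = 1.5

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("spot diameter must be > 0")
        if self.frac_contact < 0 or self.frac_engulfed < 0 or \
                self.frac_contact + self.frac_engulfed > 1.0:
            raise ValueError("planted fractions must be >= 0 and sum <= 1")


@dataclass(frozen=True)
class CD68Model:
    """Lysosomal puncta planted inside cell masks."""

    puncta_per_cell: int = 5
    radius: float = 0.3
    intensity: float = 80.0


@dataclass(frozen=True)
class NoiseModel:
    """Poisson (photon) then additive Gaussian (read) noise."""

    read_sd: float = 5.0
    photon_scale: float | None = 10.0


# ---------------------------------------------------------------------------
# growth


@dataclass
class GrownCell:
    skeleton: SkeletonGraph
    model: GliaModel
    true_length: float
    n_branch_points: int
    cell_id: int = 1


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def grow_glia(model: GliaModel, seed) -> GrownCell:
    """Grow one glial tree; deterministic for a fixed seed.

    Returns a soma-rooted skeleton in µm coordinates whose recorded true
    length is exactly the sum of edge lengths.
    """
    rng = np.random.default_rng(seed)
    center = np.asarray(model.soma_center if model.soma_center is not None else (0.0, 0.0, 0.0), float)
    nodes = [center.copy()]
    edges: list[tuple[int, int]] = []
    n_branches = 0
    total = 0.0

    # primary processes emanate from the soma surface; the connector edge
    # from the soma center keeps the tree rooted but its (intra-soma)
    # length is not part of the process length
    queue = []
    for _ in range(model.n_primary):
        d0 = _unit(rng.standard_normal(3))
        nodes.append(center + d0 * model.soma_radius)
        edges.append((0, len(nodes) - 1))
        queue.append((len(nodes) - 1, d0, 1))
    qi = 0
    while qi < len(queue):
        start, direction, depth = queue[qi]
        qi += 1
        if model.segment_cv == 0:
            seg_len = model.mean_segment
        else:
            shape = 1.0 / model.segment_cv**2
            seg_len = rng.gamma(shape, model.mean_segment / shape)
        remaining = seg_len
        cur = start
        d = direction.copy()
        while remaining > 1e-9:
            stl = min(model.step, remaining)
            if model.tortuosity > 0:
                d = _unit(d + model.tortuosity * rng.standard_normal(3))
            nodes.append(nodes[cur] + d * stl)
            edges.append((cur, len(nodes) - 1))
            cur = len(nodes) - 1
            total += stl
            remaining -= stl
        if depth < model.max_depth and rng.random() < model.branch_prob:
            n_branches += 1
            for _ in range(2):
                child = _unit(d + 0.8 * _unit(rng.standard_normal(3)))
                queue.append((cur, child, depth + 1))

    skel = SkeletonGraph(positions=np.array(nodes), edges=np.array(edges, int).reshape(-1, 2), root=0)
    return GrownCell(skeleton=skel, model=model, true_length=total, n_branch_points=n_branches)


# ---------------------------------------------------------------------------
# rasterisation and rendering


def _stamp_balls(mask: np.ndarray, centers_um: np.ndarray, radius: float, grid: VoxelGrid) -> int:
    """Mark voxels whose centers lie within ``radius`` of any center.
    Returns the number of centers that fell outside the grid entirely."""
    vs = np.asarray(grid.voxel_size)
    shape = np.asarray(grid.shape)
    clipped = 0
    for p in np.atleast_2d(centers_um):
        lo = np.floor((p - radius) / vs - 0.5).astype(int)
        hi = np.ceil((p + radius) / vs - 0.5).astype(int) + 1
        lo_c = np.maximum(lo, 0)
        hi_c = np.minimum(hi, shape)
        if np.any(lo_c >= hi_c):
            clipped += 1
            continue
        ax = [np.arange(a, b) for a, b in zip(lo_c, hi_c)]
        zz, yy, xx = np.meshgrid(*ax, indexing="ij")
        cz = (zz + 0.5) * vs[0] - p[0]
        cy = (yy + 0.5) * vs[1] - p[1]
        cx = (xx + 0.5) * vs[2] - p[2]
        ball = cz**2 + cy**2 + cx**2 <= radius**2
        mask[lo_c[0]:hi_c[0], lo_c[1]:hi_c[1], lo_c[2]:hi_c[2]] |= ball
    return clipped


def rasterize_cell(cell: GrownCell, grid: VoxelGrid) -> tuple[CellMask, float]:
    """Union of process tubes and the soma ball as a voxel mask.

    Returns the mask and the fraction of skeleton sample points clipped
    by the grid boundary (recorded in ground truth).
    """
    skel = cell.skeleton
    spacing = min(grid.voxel_size) / 2.0
    samples = []
    for a, b in skel.edges:
        pa, pb = skel.positions[a], skel.positions[b]
        n = max(int(np.ceil(np.linalg.norm(pb - pa) / spacing)), 1)
        t = np.arange(n + 1) / n
        samples.append(pa[None, :] + t[:, None] * (pb - pa)[None, :])
    pts = np.vstack(samples) if samples else skel.positions[[skel.root]]

    extent = np.asarray(grid.physical_extent)
    inside = np.all((pts >= 0) & (pts <= extent), axis=1)
    clipped_fraction = 1.0 - float(inside.mean())

    mask = np.zeros(grid.shape, dtype=bool)
    _stamp_balls(mask, pts, cell.model.process_radius, grid)
    _stamp_balls(mask, skel.positions[skel.root][None, :], cell.model.soma_radius, grid)
    return CellMask(mask=mask, soma_um=skel.positions[skel.root].copy(), cell_id=cell.cell_id), clipped_fraction


@dataclass
class SceneGroundTruth:
    """Everything the generator knows about one rendered scene."""

    cells: pd.DataFrame            # cell_id, true_length, n_branch_points, soma, clipped_fraction
    spots: pd.DataFrame            # z, y, x, class, distance_um, cell_id
    cd68: pd.DataFrame             # cell_id, true_volume_um3
    masks: list[CellMask] = field(default_factory=list)
    skeletons: list[SkeletonGraph] = field(default_factory=list)

    @property
    def engulfed_fraction(self) -> float:
        if len(self.spots) == 0:
            return float("nan")
        return float((self.spots["class"] == "engulfed").mean())


def _place_spots(spot_model: SpotModel, sdf, grid: VoxelGrid, rng) -> pd.DataFrame:
    """Plant spot centroids at voxel centers with controlled signed distance."""
    vol = float(np.prod(grid.physical_extent))
    total = int(round(spot_model.density_per_um3 * vol))
    n_eng = int(round(spot_model.frac_engulfed * total))
    n_con = int(round(spot_model.frac_contact * total))
    n_free = total - n_eng - n_con

    shape = np.asarray(grid.shape)
    vs = np.asarray(grid.voxel_size)
    centers = (np.indices(grid.shape).reshape(3, -1).T + 0.5) * vs
    margin_ok = np.all(
        (centers >= spot_model.border_margin) &
        (centers <= np.asarray(grid.physical_extent) - spot_model.border_margin),
        axis=1,
    )
    if sdf is not None:
        d = sdf.field.ravel()
    else:
        d = np.full(len(centers), np.inf)

    pools = {
        "engulfed": margin_ok & (d > -0.45) & (d < -0.05),
        "contact": margin_ok & (d > 0.05) & (d < 0.95),
        "free": margin_ok & (d > spot_model.free_min_distance),
    }
    wanted = {"engulfed": n_eng, "contact": n_con, "free": n_free}

    accepted: list[np.ndarray] = []
    rows = []
    for cat in ("engulfed", "contact", "free"):
        cand = np.flatnonzero(pools[cat])
        if wanted[cat] == 0:
            continue
        if len(cand) == 0:
            warnings.warn(f"no candidate voxels for planted class {cat!r}")
            continue
        order = rng.permutation(cand)
        n_acc = 0
        for vi in order:
            if n_acc >= wanted[cat]:
                break
            p = centers[vi]
            if accepted and np.min(np.linalg.norm(np.array(accepted) - p, axis=1)) < spot_model.min_separation:
                continue
            accepted.append(p)
            rows.append({"z": p[0], "y": p[1], "x": p[2], "planted": cat})
            n_acc += 1
        if n_acc < wanted[cat]:
            warnings.warn(f"placed only {n_acc}/{wanted[cat]} spots of class {cat!r}")

    df = pd.DataFrame(rows, columns=["z", "y", "x", "planted"])
    if len(df) and sdf is not None:
        dd = sdf.distance_at(df[["z", "y", "x"]].to_numpy())
        cls, _ = classify_point_distances(dd)
        df["distance_um"] = dd
        df["class"] = cls
        df["cell_id"] = sdf.nearest_cell_at(df[["z", "y", "x"]].to_numpy())
    else:
        df["distance_um"] = np.inf
        df["class"] = "free"
        df["cell_id"] = 0
    return df


def _add_gaussian_bumps(img: np.ndarray, pos_um: np.ndarray, amp: float,
                        sigma_um: np.ndarray, grid: VoxelGrid) -> None:
    """Add amplitude-normalised Gaussian bumps at sub-voxel positions."""
    vs = np.asarray(grid.voxel_size)
    shape = np.asarray(grid.shape)
    half = np.ceil(4.0 * sigma_um / vs).astype(int)
    for p in np.atleast_2d(pos_um):
        c = np.round(p / vs - 0.5).astype(int)
        lo = np.maximum(c - half, 0)
        hi = np.minimum(c + half + 1, shape)
        if np.any(lo >= hi):
            continue
        ax = [np.arange(a, b) for a, b in zip(lo, hi)]
        zz, yy, xx = np.meshgrid(*ax, indexing="ij")
        q = ((zz + 0.5) * vs[0] - p[0]) ** 2 / (2 * sigma_um[0] ** 2) \
            + ((yy + 0.5) * vs[1] - p[1]) ** 2 / (2 * sigma_um[1] ** 2) \
            + ((xx + 0.5) * vs[2] - p[2]) ** 2 / (2 * sigma_um[2] ** 2)
        img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amp * np.exp(-q)


def render_scene(
    cells: list[GrownCell],
    spot_model: SpotModel | None,
    grid: VoxelGrid,
    noise: NoiseModel = NoiseModel(),
    psf_sigma_um: tuple[float, float, float] = (0.25, 0.25, 0.25),
    seed: int = 0,
    cd68_model: CD68Model | None = None,
    metadata: dict | None = None,
) -> tuple[MultiChannelStack, SceneGroundTruth]:
    """Render a multi-channel stack and its complete ground truth.

    Channel "iba1" is the blurred union of cell masks; "agrp" is the sum
    of Gaussian spots of the stated physical diameter; optional "cd68" is
    blurred lysosomal puncta inside cells.  Ground truth is drawn from a
    dedicated random stream, so changing the noise model never changes it.
    """
    psf = np.asarray(psf_sigma_um, float)
    if np.any(psf <= 0):
        raise ValueError("PSF sd must be > 0")
    if noise.read_sd < 0:
        raise ValueError("read noise sd must be >= 0")
    rng_gt = np.random.default_rng([int(seed), 1])
    rng_noise = np.random.default_rng([int(seed), 2])
    vs = np.asarray(grid.voxel_size)

    masks: list[CellMask] = []
    cell_rows = []
    skeletons = []
    for cid, cell in enumerate(cells, start=1):
        cell.cell_id = cid
        m, clip = rasterize_cell(cell, grid)
        masks.append(m)
        skeletons.append(cell.skeleton)
        cell_rows.append(
            {"cell_id": cid, "true_length_um": cell.true_length,
             "n_branch_points": cell.n_branch_points,
             "soma_z": m.soma_um[0], "soma_y": m.soma_um[1], "soma_x": m.soma_um[2],
             "clipped_fraction": clip,
             "true_volume_um3": float(m.mask.sum()) * grid.voxel_volume}
        )
    cells_df = pd.DataFrame(cell_rows, columns=["cell_id", "true_length_um", "n_branch_points",
                                                "soma_z", "soma_y", "soma_x",
                                                "clipped_fraction", "true_volume_um3"])

    sdf = signed_distance(masks, grid) if masks else None

    iba1 = np.zeros(grid.shape, dtype=np.float32)
    for cell, m in zip(cells, masks):
        iba1[m.mask] = cell.model.intensity
    iba1 = ndimage.gaussian_filter(iba1, sigma=psf / vs)

    if spot_model is not None:
        spots_df = _place_spots(spot_model, sdf, grid, rng_gt)
        agrp = np.zeros(grid.shape, dtype=np.float32)
        if len(spots_df):
            sigma_eff = np.sqrt((spot_model.diameter / 4.0) ** 2 + psf**2)
            _add_gaussian_bumps(agrp, spots_df[["z", "y", "x"]].to_numpy(),
                                spot_model.intensity, sigma_eff, grid)
    else:
        spots_df = pd.DataFrame(columns=["z", "y", "x", "planted", "distance_um", "class", "cell_id"])
        agrp = np.zeros(grid.shape, dtype=np.float32)

    cd68_rows = []
    channels = {"iba1": iba1, "agrp": agrp}
    if cd68_model is not None:
        cd = np.zeros(grid.shape, dtype=bool)
        for m in masks:
            interior = np.flatnonzero(m.mask.ravel())
            if len(interior) == 0:
                cd68_rows.append({"cell_id": m.cell_id, "true_volume_um3": 0.0})
                continue
            pick = rng_gt.choice(interior, size=min(cd68_model.puncta_per_cell, len(interior)),
                                 replace=False)
            pos = (np.array(np.unravel_index(pick, grid.shape)).T + 0.5) * vs
            cell_cd = np.zeros(grid.shape, dtype=bool)
            _stamp_balls(cell_cd, pos, cd68_model.radius, grid)
            cell_cd &= m.mask  # puncta volume counted within the cell only
            cd |= cell_cd
            cd68_rows.append({"cell_id": m.cell_id,
                              "true_volume_um3": float(cell_cd.sum()) * grid.voxel_volume})
        cd68_img = ndimage.gaussian_filter(cd.astype(np.float32) * cd68_model.intensity, sigma=psf / vs)
        channels["cd68"] = cd68_img
    cd68_df = pd.DataFrame(cd68_rows, columns=["cell_id", "true_volume_um3"])

    for name in sorted(channels):
        img = channels[name]
        if noise.photon_scale:
            img = rng_noise.poisson(np.clip(img, 0, None) * noise.photon_scale).astype(np.float32) / noise.photon_scale
        if noise.read_sd > 0:
            img = img + rng_noise.normal(0.0, noise.read_sd, size=img.shape).astype(np.float32)
        channels[name] = np.clip(img, 0.0, None)

    stack = MultiChannelStack(grid=grid, channels=channels, metadata=metadata or {})
    gt = SceneGroundTruth(cells=cells_df, spots=spots_df, cd68=cd68_df,
                          masks=masks, skeletons=skeletons)
    return stack, gt


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSpec:
    """A two-(or more-)group cohort of simulated animals.

    ``groups`` maps group name to parameter overrides, e.g.
    ``{"NCD": {}, "MHFD": {"glia": {"mean_segment": 7.48}}}``.
    ``animal_cv`` is the lognormal coefficient of variation of the
    per-animal multipliers applied to the mean segment length and the
    terminal density (biological between-animal variability).
    """

    groups: dict[str, dict] = field(default_factory=lambda: {"NCD": {}, "MHFD": {}})
    animals_per_group: int = 4
    stacks_per_animal: int = 1
    shape: tuple[int, int, int] = (144, 144, 144)
    voxel_size: tuple[float, float, float] = (0.3, 0.3, 0.3)
    base_glia: GliaModel = field(default_factory=GliaModel)
    base_spots: SpotModel = field(default_factory=SpotModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    psf_sigma_um: tuple[float, float, float] = (0.25, 0.25, 0.25)
    animal_cv: float = 0.10
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.animals_per_group < 2:
            raise ValueError("need >= 2 animals per group")
        if not self.groups:
            raise ValueError("need at least one group")

    def group_models(self, group: str) -> tuple[GliaModel, SpotModel]:
        ov = self.groups[group]
        glia = replace(self.base_glia, **ov.get("glia", {}))
        spots = replace(self.base_spots, **ov.get("spots", {}))
        return glia, spots


def two_group_spec(
    length_ratio: float = 1.87,
    density_ratio: float = 1.61,
    animals_per_group: int = 20,
    master_seed: int = 0,
    **kwargs,
) -> CohortSpec:
    """Reference two-group cohort with planted effect sizes.

    Group "MHFD" carries a ``length_ratio`` increase in mean segment
    length (hence expected total process length) and a ``density_ratio``
    increase in terminal density over the "NCD" reference group.
    """
    base = kwargs.pop("base_glia", GliaModel())
    base_spots = kwargs.pop("base_spots", SpotModel())
    groups = {
        "NCD": {},
        "MHFD": {
            "glia": {"mean_segment": base.mean_segment * length_ratio},
            "spots": {"density_per_um3": base_spots.density_per_um3 * density_ratio},
        },
    }
    return CohortSpec(groups=groups, animals_per_group=animals_per_group,
                      base_glia=base, base_spots=base_spots,
                      master_seed=master_seed, **kwargs)


@dataclass
class CohortData:
    """In-memory result of :func:`generate_cohort`."""

    spec: CohortSpec
    stacks: list[MultiChannelStack]
    ground_truths: list[SceneGroundTruth]
    index: pd.DataFrame  # group, animal, stack, seed per rendered stack
    paths: list[Path] = field(default_factory=list)


def _animal_multipliers(rng, cv: float) -> tuple[float, float]:
    if cv <= 0:
        return 1.0, 1.0
    sigma = np.sqrt(np.log(1.0 + cv**2))
    mu = -0.5 * sigma**2  # unit mean
    return float(np.exp(rng.normal(mu, sigma))), float(np.exp(rng.normal(mu, sigma)))


def generate_cohort(spec: CohortSpec, out_dir: str | Path | None = None,
                    cd68_model: CD68Model | None = None) -> CohortData:
    """Simulate every stack of a cohort; deterministic under the master seed.

    Per-animal random streams are ``default_rng([master_seed, group_index,
    animal_index, stack_index])``; the per-animal biological multipliers
    use the stream with stack index −1.  With ``out_dir`` set, stacks are
    written as OME-TIFF and ground truth as CSV tables.
    """
    grid = VoxelGrid(shape=spec.shape, voxel_size=spec.voxel_size)
    stacks, gts, rows, paths = [], [], [], []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    for gi, group in enumerate(sorted(spec.groups)):
        glia_g, spots_g = spec.group_models(group)
        for ai in range(spec.animals_per_group):
            rng_bio = np.random.default_rng([spec.master_seed, gi, ai, 2**16])
            m_len, m_den = _animal_multipliers(rng_bio, spec.animal_cv)
            glia_a = replace(glia_g, mean_segment=glia_g.mean_segment * m_len)
            spots_a = replace(spots_g, density_per_um3=spots_g.density_per_um3 * m_den)
            animal = f"{group}_{ai:02d}"
            for si in range(spec.stacks_per_animal):
                seed = [spec.master_seed, gi, ai, si]
                center = tuple(e / 2.0 for e in grid.physical_extent)
                cell = grow_glia(replace(glia_a, soma_center=center),
                                 np.random.default_rng(seed + [0]))
                meta = {"animal": animal, "group": group, "region": "SIM", "age": "P16",
                        "stack": str(si)}
                stack, gt = render_scene([cell], spots_a, grid, noise=spec.noise,
                                         psf_sigma_um=spec.psf_sigma_um,
                                         seed=int(np.random.default_rng(seed + [1]).integers(2**31)),
                                         cd68_model=cd68_model, metadata=meta)
                stacks.append(stack)
                gts.append(gt)
                rows.append({"group": group, "animal": animal, "stack": si,
                             "true_length_um": float(gt.cells["true_length_um"].sum()),
                             "n_true_spots": len(gt.spots),
                             "n_true_engulfed": int((gt.spots["class"] == "engulfed").sum())})
                if out is not None:
                    p = out / f"{animal}_s{si}.ome.tif"
                    write_stack(stack, p)
                    paths.append(p)

    index = pd.DataFrame(rows)
    if out is not None:
        index.to_csv(out / "ground_truth_index.csv", index=False)
        pd.concat(
            [g.spots.assign(animal=r["animal"], stack=r["stack"])
             for g, (_, r) in zip(gts, index.iterrows())],
            ignore_index=True,
        ).to_csv(out / "ground_truth_spots.csv", index=False)
    return CohortData(spec=spec, stacks=stacks, ground_truths=gts, index=index, paths=paths)


def simulate_animal_lengths(
    model: GliaModel,
    n_animals: int,
    seed,
    stacks_per_animal: int = 1,
    animal_cv: float = 0.10,
) -> np.ndarray:
    """Per-animal mean true process length from the generator alone.

    This is the ground-truth-level sampler used for statistical power and
    calibration simulations: no rasterisation or imaging, just the tree
    growth law and the between-animal lognormal variability.
    """
    rng = np.random.default_rng(seed)
    vals = np.empty(n_animals)
    for a in range(n_animals):
        m_len, _ = _animal_multipliers(rng, animal_cv)
        m = replace(model, mean_segment=model.mean_segment * m_len)
        lengths = [grow_glia(m, rng).true_length for _ in range(stacks_per_animal)]
        vals[a] = float(np.mean(lengths))
    return vals
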