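"""Validation experiments on synthetic ground truth.

These functions run the measurement pipeline against the simulator's
ground truth and summarise the agreement: spot-detection precision and
recall, planted-effect recovery through the full imaging chain, classifier
agreement on true centroids, and statistical calibration of the group
report.  They are used by the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grid import ROI, VoxelGrid
from .interaction import classify_spots, signed_distance
from .morphometry import measure_cells, segment_cells
from .spots import detect_spots
from .stats import unpaired_t_test
from .synth import (
    CohortSpec,
    GliaModel,
    NoiseModel,
    SpotModel,
    generate_cohort,
    grow_glia,
    render_scene,
    simulate_animal_lengths,
)

__all__ = [
    "match_points",
    "detection_benchmark",
    "cohort_recovery",
    "classifier_agreement",
    "power_simulation",
    "type1_simulation",
]


def match_points(detected: np.ndarray, truth: np.ndarray, radius: float) -> int:
    """Number of one-to-one matches within ``radius`` (greedy nearest-first)."""
    detected = np.atleast_2d(detected)
    truth = np.atleast_2d(truth)
    if len(detected) == 0 or len(truth) == 0:
        return 0
    tree = cKDTree(truth)
    pairs = []
    for i, p in enumerate(detected):
        for j in tree.query_ball_point(p, radius):
            pairs.append((float(np.linalg.norm(p - truth[j])), i, j))
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    n = 0
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        n += 1
    return n


def detection_benchmark(
    n_stacks: int = 20,
    n_spots: int = 50,
    snr: float = 10.0,
    seed: int = 0,
    shape: tuple[int, int, int] = (96, 96, 96),
    voxel_size: tuple[float, float, float] = (0.2, 0.2, 0.2),
    match_radius: float = 0.4,
) -> dict:
    """Precision/recall of spot detection on planted non-overlapping spots.

    Each stack contains exactly ``n_spots`` free spots of 0.8 µm diameter;
    SNR is the rendered peak amplitude over the Gaussian read-noise sd.
    """
    grid = VoxelGrid(shape=shape, voxel_size=voxel_size)
    vol = float(np.prod(grid.physical_extent))
    read_sd = 10.0
    spot_model = SpotModel(
        intensity=snr * read_sd,
        density_per_um3=n_spots / vol,
        frac_contact=0.0,
        frac_engulfed=0.0,
        free_min_distance=0.0,
    )
    noise = NoiseModel(read_sd=read_sd, photon_scale=None)
    tp = fp = fn = 0
    for s in range(n_stacks):
        stack, gt = render_scene([], spot_model, grid, noise=noise,
                                 seed=int(np.random.default_rng([seed, s]).integers(2**31)))
        spots = detect_spots(stack.channel("agrp"), grid)
        det = spots.centroids_um()
        tru = gt.spots[["z", "y", "x"]].to_numpy()
        m = match_points(det, tru, match_radius)
        tp += m
        fp += len(det) - m
        fn += len(tru) - m
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return {"precision": precision, "recall": recall, "tp": tp, "fp": fp, "fn": fn,
            "n_stacks": n_stacks, "n_spots": n_spots * n_stacks}


def cohort_recovery(spec: CohortSpec, reference_group: str = "NCD",
                    test_group: str = "MHFD") -> dict:
    """Run the full imaging + measurement chain on a simulated cohort and
    compare per-group means of the measured metrics.

    Returns measured and ground-truth group ratios (test / reference) for
    process length and terminal density, plus the measured engulfed
    fraction against the planted one, and the length t-test.
    """
    cohort = generate_cohort(spec)
    rows = []
    for stack, gt in zip(cohort.stacks, cohort.ground_truths):
        grid = stack.grid
        roi = ROI.full(grid)
        cells = segment_cells(stack.channel("iba1"), grid, min_volume_um3=20.0)
        mt = measure_cells(cells, grid)
        spots = detect_spots(stack.channel("agrp"), grid)
        if cells and spots.count:
            sdf = signed_distance(cells, grid)
            rec = classify_spots(spots, sdf)
            engulfed_frac = float((rec["class"] == "engulfed").mean())
        else:
            engulfed_frac = float("nan")
        rows.append({
            "group": stack.metadata["group"],
            "animal": stack.metadata["animal"],
            "measured_length": float(mt["process_length_um"].sum()),
            "measured_complexity": float(mt["sholl_complexity"].sum()),
            "n_spots": spots.count,
            "true_length": float(gt.cells["true_length_um"].sum()),
            "n_true_spots": len(gt.spots),
            "true_engulfed_frac": gt.engulfed_fraction,
            "engulfed_frac": engulfed_frac,
        })
    df = pd.DataFrame(rows)
    per_animal = df.groupby(["group", "animal"], sort=True).mean(numeric_only=True).reset_index()
    ga = per_animal[per_animal["group"] == reference_group]
    gb = per_animal[per_animal["group"] == test_group]

    out = {
        "measured_length_ratio": gb["measured_length"].mean() / ga["measured_length"].mean(),
        "true_length_ratio": gb["true_length"].mean() / ga["true_length"].mean(),
        "measured_density_ratio": gb["n_spots"].mean() / ga["n_spots"].mean(),
        "true_density_ratio": gb["n_true_spots"].mean() / ga["n_true_spots"].mean(),
        "measured_complexity_ratio": gb["measured_complexity"].mean() / ga["measured_complexity"].mean(),
        "engulfed_fraction_measured": float(df["engulfed_frac"].mean()),
        "engulfed_fraction_true": float(df["true_engulfed_frac"].mean()),
        "n_animals_per_group": spec.animals_per_group,
    }
    cmp_ = unpaired_t_test(ga["measured_length"], gb["measured_length"],
                           metric="process_length")
    out["length_p_value"] = cmp_.p
    out["length_percent_change"] = cmp_.percent_change
    return out


def classifier_agreement(n_scenes: int = 50, seed: int = 0,
                         shape: tuple[int, int, int] = (64, 64, 64),
                         voxel_size: tuple[float, float, float] = (0.3, 0.3, 0.3)) -> dict:
    """Agreement of the spot classifier with ground-truth classes when run
    on the true centroids (shared-definition check; must be exact)."""
    grid = VoxelGrid(shape=shape, voxel_size=voxel_size)
    center = tuple(e / 2 for e in grid.physical_extent)
    n_total = n_agree = 0
    for s in range(n_scenes):
        cell = grow_glia(GliaModel(soma_center=center, mean_segment=3.0),
                         np.random.default_rng([seed, s]))
        stack, gt = render_scene([cell], SpotModel(density_per_um3=0.002,
                                                   frac_contact=0.15, frac_engulfed=0.15),
                                 grid, seed=int(np.random.default_rng([seed, s, 1]).integers(2**31)))
        if len(gt.spots) == 0:
            continue
        sdf = signed_distance(gt.masks, grid)
        rec = classify_spots(gt.spots[["z", "y", "x"]].to_numpy(), sdf)
        n_total += len(rec)
        n_agree += int((rec["class"].to_numpy() == gt.spots["class"].to_numpy()).sum())
    return {"n_spots": n_total, "n_agree": n_agree,
            "disagreement": (n_total - n_agree) / n_total if n_total else float("nan")}


def power_simulation(
    n_cohorts: int = 200,
    n_per_group: int = 20,
    length_ratio: float = 1.87,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Fraction of simulated cohorts in which the planted process-length
    effect is detected (p < alpha) and the mean recovered ratio.

    Runs at generator ground-truth level: per-animal true lengths from the
    growth law with between-animal variability, no imaging.
    """
    base = GliaModel()
    alt = replace(base, mean_segment=base.mean_segment * length_ratio)
    detected = 0
    ratios = np.empty(n_cohorts)
    for c in range(n_cohorts):
        a = simulate_animal_lengths(base, n_per_group, [seed, c, 0])
        b = simulate_animal_lengths(alt, n_per_group, [seed, c, 1])
        cmp_ = unpaired_t_test(a, b)
        detected += cmp_.p < alpha
        ratios[c] = b.mean() / a.mean()
    return {"power": detected / n_cohorts, "mean_ratio": float(ratios.mean()),
            "n_cohorts": n_cohorts, "n_per_group": n_per_group}


def type1_simulation(
    n_comparisons: int = 1000,
    n_per_group: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Empirical type-I error of the unpaired t-test under a planted null
    (identical generator parameters in both groups)."""
    base = GliaModel()
    rejected = 0
    for c in range(n_comparisons):
        a = simulate_animal_lengths(base, n_per_group, [seed, c, 0])
        b = simulate_animal_lengths(base, n_per_group, [seed, c, 1])
        rejected += unpaired_t_test(a, b).p < alpha
    return {"type1_error": rejected / n_comparisons, "n_comparisons": n_comparisons,
            "n_per_group": n_per_group}
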