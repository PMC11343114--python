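# gliamorph

Quantitative 3D analysis of microglia and their interactions with axon
terminals in multi-channel confocal stacks — the kind of measurement done
when asking whether microglia in a developing brain region have changed
their morphology or are engulfing synaptic terminals.

Given stacks with an Iba1 (microglia) channel, a terminal channel (e.g.
synaptophysin-tdTomato–labelled AgRP axons) and optionally a CD68
(lysosome) channel, the package:

* segments individual microglia and measures, per cell, the **total
  process length** L = Σᵢ ‖eᵢ‖ over the edges of the 3D skeleton, the
  **Sholl branching complexity** (crossings of concentric spheres of
  radius r around the soma, summed over r), the **cell volume** and the
  **convex-hull territory volume**;
* detects terminals as fixed-diameter (0.8 µm) **spots** via a
  scale-normalised 3D Mexican-hat (Laplacian-of-Gaussian) filter at
  σ = r/√3, thresholded by an exact 1-D two-means split of the candidate
  responses;
* classifies each spot by its signed distance d to the nearest microglial
  surface (positive outside): **contact** if |d| ≤ 1 µm, **engulfed** if
  the centroid lies within 0.5 µm inside the surface (both the literal
  shell reading and a full-interior reading are available), **free**
  otherwise; CD68⁺ volume inside each cell is quantified the same way;
* aggregates everything to one value per animal and compares groups with
  unpaired two-sided t-tests, reporting mean ± SEM and percent change.

Because real acquisitions of this kind are rarely shared, the package
includes a first-class synthetic-microscopy module: procedurally grown
branching glia and planted spots rendered through a Gaussian PSF with
Poisson + Gaussian noise, with complete ground truth (true skeletons,
lengths, spot classes).  Every measurement stage is validated against
that ground truth or an independent brute-force oracle.

## Worked example

```python
from gliamorph import (GliaModel, SpotModel, VoxelGrid, grow_glia,
                       render_scene, segment_cells, measure_cells,
                       detect_spots, signed_distance, classify_spots)

grid = VoxelGrid(shape=(144, 144, 144), voxel_size=(0.3, 0.3, 0.3))  # µm
cell = grow_glia(GliaModel(soma_center=(21.6, 21.6, 21.6)), seed=1)
stack, truth = render_scene([cell], SpotModel(), grid, seed=3)

cells = segment_cells(stack.channel("iba1"), grid, min_volume_um3=20)
print(measure_cells(cells, grid)[["process_length_um", "sholl_complexity",
                                  "cell_volume_um3", "territory_volume_um3"]])
#    process_length_um  sholl_complexity  cell_volume_um3  territory_volume_um3
# 0          36.187132                28           79.164               140.976
print(f"true length {truth.cells.true_length_um[0]:.1f}")
# true length 41.4

spots = detect_spots(stack.channel("agrp"), grid)
field = signed_distance(cells, grid)
records = classify_spots(spots, field)
print(records["class"].value_counts().to_dict(), "| truth:",
      truth.spots["class"].value_counts().to_dict())
# {'free': 219, 'contact': 14, 'engulfed': 9} | truth: {'free': 218, 'engulfed': 12, 'contact': 12}
```

The measured skeleton length (36.2 µm) sits a bit below the true
grown length (41.4 µm) — thinning always loses a little length at
process tips and inside the soma — and the distance classifier recovers
the planted contact/engulfed structure up to surface-localisation error
of about half a voxel.

A full simulated two-group study (cohort simulation → segmentation →
morphometry → spot detection → classification → per-animal group report)
runs from one config:

```bash
gliamorph run-all --out out/ --seed 7      # or: --config run.yaml
cat out/group_report.csv
```

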