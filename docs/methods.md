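# Methods

This note documents the models, algorithms and numerical choices behind
gliamorph, and what the synthetic validation does and does not show.

## Coordinate and unit conventions

Everything is ordered `(z, y, x)`. Voxel indices are 0-based; the
physical position of voxel `(k, j, i)` is its center,
`((k+0.5)·dz, (j+0.5)·dy, (i+0.5)·dx)` µm. Voxel sizes are required
metadata: a stack without physical voxel sizes (and without an explicit
override) is rejected, because a silently assumed voxel size corrupts
every downstream µm quantity. Anisotropy is permitted everywhere;
distances are always computed with per-axis physical scaling. ROIs are
supplied explicitly (bounds or masks), never inferred from a nuclear
stain.

## Cell segmentation

The microglia channel is background-subtracted (Gaussian estimate,
sd 8 µm by default) and Gaussian-smoothed (sd 0.4 µm) before
thresholding — punctate-noise suppression that the usual confocal
workflow applies to both channels. The threshold is the exact 1-D
two-means split of the ROI intensities: because the optimal two-cluster
partition of scalars is contiguous in sorted order, the global optimum
is found by a prefix-sum scan over all sorted splits, with no iterative
heuristic and no dependence on initialisation. Suprathreshold voxels are
grouped into 26-connected components; components below a minimum volume
(default 50 µm³ for real acquisitions; 20 µm³ in the scaled-down
simulations) are discarded. The soma centroid is the interior maximum of
the anisotropy-aware Euclidean distance transform of the mask — a
standard, robust proxy for the cell body when no separate soma marker
exists.

## Skeletonisation and morphometry

Anisotropic masks are first resampled (nearest-neighbour) to isotropic
voxels at the smallest voxel dimension so thinning is not axis-biased.
The mask is thinned to a one-voxel medial representation and converted
to a spatial graph: skeleton voxels are nodes at their physical centers,
26-neighbour pairs are edges weighted by Euclidean length. Cycles
introduced by thinning are broken by removing the longest edge of each
cycle (equivalently, a minimum spanning tree). The root is the node
nearest the soma centroid; terminal spurs shorter than a prune length
(default 1 µm) are removed iteratively, so thinning artifacts do not
inflate branch counts. One edge case: the thinning implementation can
annihilate masks with perfectly even mirror symmetry (a synthetic
hazard, not a realistic one); when the skeleton of a non-trivial mask
comes back empty, the mask is re-thinned at 2× resampling, which breaks
the degeneracy.

Per-cell metrics:

* **Process length** — sum of skeleton edge lengths. On synthetic tubes
  this is accurate to a few percent; thinning loses ~one tube radius at
  each tip and gains a little inside the soma blob.
* **Sholl profile** — for each radius r (default 1 µm steps up to the
  maximal node distance), the exact number of intersections of the
  sphere of radius r centred on the root with the skeleton's edge
  segments, from the quadratic `|u + t v|² = r²` per edge counted on
  t ∈ [0, 1). An edge crossing a sphere twice counts twice. The summary
  "branching complexity" is the sum of counts over all radii — the
  closest literal reading of counting every process–sphere contact — and
  the full profile is always kept alongside, since other summaries
  (maximum, area under profile) are linear functionals of it.
* **Cell volume** — mask voxel count × voxel volume.
* **Territory volume** — volume of the 3D convex hull of the skeleton
  nodes plus the soma centroid (the mask surface voxels are available as
  an alternative point source). Degenerate (coplanar) point sets raise
  an error rather than returning 0.
* **Density** — somata whose centroid falls inside the ROI, divided by
  the ROI's physical volume (reported per 10⁶ µm³, with the raw count).

## Spot detection

Terminals are modelled as spots of fixed physical diameter (default
0.8 µm). The channel is background-subtracted (Gaussian sd = 5 ×
diameter) and pre-smoothed (sd = radius/2), then filtered with a
scale-normalised 3D Laplacian-of-Gaussian ("Mexican hat") at
σ = radius/√3 per axis — the standard blob-optimal correspondence
between a ball of radius r and the LoG scale in 3D. Candidates are
26-connected local maxima of the response (plateau ties resolved to the
lexicographically smallest index, for determinism); maxima within one
spot radius of the stack border are flagged and not retained, since
truncated spots bias centroids. The automatic threshold is the exact
two-means split of the candidate responses — thresholding detections
rather than all voxels is far better conditioned, because the candidate
population is small and genuinely bimodal (noise maxima vs. spots) in
realistic images. When that population is effectively unimodal (the
lower cluster mean exceeds half the upper — e.g. a noiseless image
containing only true spots), no threshold is applied: there is no noise
population to reject, and splitting would arbitrarily discard half the
spots. A manual threshold is available, and the spot count is monotone
non-increasing in it. Centroids are refined by an intensity-weighted
mean over the spot-radius neighbourhood, giving sub-voxel accuracy
(≤ 0.5 voxel in the benchmark).

## Contact and engulfment classification

The cell-surface voxel layer (mask voxels with a 6-neighbour outside the
mask; the image border is not a surface) defines a signed Euclidean
distance field: zero on surface voxels, positive outside, negative
inside, with per-axis physical scaling. Each retained spot is classified
by the trilinear interpolation of this field at its centroid, against
the nearest cell only:

* **engulfed** — shell mode (default): −0.5 µm < d ≤ 0, the literal
  "within half a micron inside the surface" rule; full-interior mode:
  d ≤ 0. Spots deeper than the shell are always flagged
  `deep_interior`, so both readings remain reportable — the literal
  shell rule excludes deeply internalised spots, which is biologically
  surprising, and the ambiguity cannot be resolved from the rule
  statement alone.
* **contact** — not engulfed and |d| ≤ 1 µm. The rule is applied to
  |d| so a centroid just inside the surface but outside the engulfment
  shell still counts as contact; a one-sided reading would leave a
  classification gap at d = 0.
* **free** — otherwise.

Every spot receives exactly one class. CD68⁺ volume is quantified
inside the union of cell masks by the same two-means threshold applied
to the in-mask CD68 intensities; suprathreshold voxel volume is
reported per cell and per ROI, and can never exceed the cell volume.

## Group statistics

The animal is the statistical unit everywhere: cell- and spot-level
values are first averaged within animal, so the group mean is the
unweighted mean of animal means, never the pooled cell mean. Groups are
compared with unpaired two-sided t-tests (Student by default, matching
the common Prism default when only "unpaired t-test" is stated; Welch by
flag — the two agree exactly for equal sizes and variances). Summaries
are mean ± SEM (sample sd/√n) with percent change
100·(mean_B − mean_A)/mean_A. No multiple-testing correction is applied,
and the report footer says so. With fewer than two animals per group no
test is computed; SEM of a single value is reported as missing.

## Synthetic microscopy

The simulator provides the ground truth that real acquisitions of this
kind lack.

**Growth.** A glial cell is a soma ball plus a stochastic tree:
`n_primary` processes leave the soma surface in uniformly random
directions; each grows as a persistent random walk (0.5 µm steps whose
direction is perturbed by Gaussian noise of sd `tortuosity` = 0.15,
chosen so processes are smooth at the tube-radius scale, as real
processes are) for a gamma-distributed arc length (mean 4 µm in the
reference group, CV 0.25); at each arc-length interval end the process
either branches into two daughters (probability 0.8 while the branch
depth is below 2) or terminates. This law was chosen because its
expected segment and branch counts have closed recursive forms
(S(d) = 1 + 2p·S(d+1), B(d) = p(1 + 2B(d+1))), which the tests use as
enumeration oracles against Monte-Carlo means. The recorded true length
is exactly the summed step length of the grown processes; the
soma-center connector edges are part of the rooted skeleton but not of
the process length.

**Rendering.** Cells are rasterised as the union of radius-0.5 µm tubes
stamped along the skeleton plus the soma ball (radius 2 µm), scaled so a
cell clears the default 20 µm³ minimum-volume filter used at this scale.
The microglia channel is the mask at intensity 100 blurred by a
separable Gaussian PSF (sd 0.25 µm per axis); spots are
amplitude-normalised Gaussians (σ combining the 0.8 µm spot size and the
PSF) added at sub-voxel positions; optional CD68 puncta are small balls
planted inside cell masks. Noise is Poisson (photon scaling 10 per
intensity unit) followed by Gaussian read noise (sd 5), then clipping at
zero. Ground truth is drawn from a random stream separate from the
noise stream, so changing the noise model never changes ground truth.

**Spot planting.** Spots are placed at voxel centers drawn from pools
defined by the same signed-distance field the classifier uses: engulfed
in the interior shell (−0.45, −0.05) µm, contacts in (0.05, 0.95) µm,
free beyond 1.5 µm, with a 1.6 µm minimum separation, a 1.5 µm border
margin, and default fractions 5% engulfed / 5% contact at 0.003
spots/µm³. Ground-truth classes are then *recomputed* by the package's
own classification rule on the true centroids — a deliberately shared
definition, so the classifier can be required to agree with ground truth
exactly when given true geometry.

**Cohorts.** A cohort spec maps group names to parameter overrides; the
reference two-group design plants a 1.87× mean-segment-length ratio
(hence a 1.87× expected process length, an 87% increase) and a 1.61×
terminal-density ratio in the "MHFD" group over the "NCD" reference.
Between-animal biological variability is a lognormal multiplier
(CV 10%, unit mean) on segment length and terminal density. Per-animal
streams derive from `default_rng([master_seed, group, animal, stack])`,
so cohorts are bit-reproducible and animals independent; regenerating a
written cohort produces byte-identical OME-TIFFs (the embedded OME UUID
is content-derived).

**Problem sizes.** Simulated stacks are 144³ voxels at 0.3 µm
isotropic (43.2 µm field), with cells (≈ 40 µm process length in the
reference group) an order of magnitude smaller than adult microglia —
a deliberate scaled-down geometry in which one cell plus its terminal
field fits a single stack without clipping (the 1.87× group's expected
radial extent, ~2 segments × 7.5 µm plus tails, stays inside the half
field of 21.6 µm). The validation cohort uses 20 animals per group, one
stack per animal; power and calibration simulations run at generator
level (true lengths, no rendering), 200 cohorts for power and 1000
comparisons for type-I error.

## What the validation shows — and does not

Exact checks: Sholl counts against dense-sampling sign changes; hull
volumes against brute-force facet enumeration with the divergence
theorem; the two-means threshold against exhaustive split enumeration;
signed distances against direct nearest-boundary search (within half a
voxel diagonal); classification against ground truth with zero
disagreement on true centroids. Stochastic checks: ≥ 95% precision and
recall for planted 0.8 µm spots at SNR 10; recovery of the planted group
ratios through the full imaging chain within ±15%; ≥ 95% power for the
planted length effect at n = 20/group; t-test type-I error within
[0.03, 0.07] under a planted null.

These results demonstrate that the *measurement chain is correct and
calibrated under the simulator's assumptions*. They do not demonstrate
robustness to what the simulator omits: vascular and autofluorescent
background, spectral bleed-through, touching or overlapping cells,
depth-dependent PSF and attenuation, motion or sectioning artifacts, and
truly ramified adult morphology. Measured process length carries a small
systematic bias (thinning loses ~a tube radius per tip and slightly
overshoots through the soma), which partially cancels in group ratios
but should be kept in mind for absolute values. The engulfment counts
inherit surface-localisation error of about half a voxel; spots planted
within that distance of the class boundaries can flip class after
imaging.

## Degenerate inputs and tie-breaking

Flat channels segment to zero cells; a two-means threshold of identical
values is an error ("degenerate distribution"); hulls of coplanar points
are errors, and cells whose hull degenerates report territory 0 with a
warning rather than aborting a cohort run. Plateau maxima and spanning
tree ties resolve by lexicographic voxel order. Zero detected spots
yield an engulfed fraction of NaN with a warning (never 0, which would
understate uncertainty). All pipeline tables are written with fixed
column order, fixed float formatting and a config-hash header line, so
a rerun with the same config and seed is byte-identical.
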