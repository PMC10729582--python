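# Methods

This note documents the models, conventions and numerical choices behind
`gliavasc`, what the synthetic-data generator does and does not emulate,
and the known limitations of each stage.

## Vessel enhancement and segmentation

The vessel channel is enhanced with the multi-scale Frangi vesselness
filter. At each scale σ ∈ {1, 2, 3, 4, 5} pixels the Hessian is computed on
the Gaussian-smoothed image by central finite differences and
scale-normalized by σ² (the standard Lindeberg factor); eigenvalues are
sorted by absolute value. The 2D response is
exp(−R_B²/2β²)·(1 − exp(−S²/2γ²)) for λ₂ < 0, and the 3D response adds the
plate discriminator (1 − exp(−R_A²/2α²)) for λ₂, λ₃ < 0, with
R_A = |λ₂|/|λ₃|, R_B = |λ₁|/√|λ₂λ₃|, S = ‖λ‖₂. Polarity is fixed to bright
tubes on dark background (fluorescence).

**Self-tuned γ.** γ is not a free parameter: it is 0.4 × the maximum
absolute Hessian eigenvalue over the *whole image and all scales*, computed
once per image (the image has one global contrast, so one γ). α = β = 0.5,
the conventional defaults; both are exposed.

**Thresholds.** The vesselness distribution (256 equal-width bins over the
finite range, zeros included) is split by exhaustive three-class Otsu —
every pair of cut points is scored by between-class variance; near-equal
scores (within 10⁻¹² relative, which arise on empty-bin plateaus) count as
ties and resolve to the lexicographically smallest (low, high). The low and
high cuts feed hysteresis segmentation: the mask is the union of connected
components of {v > low} that contain at least one voxel with v ≥ high.
Connectivity is the most permissive standard choice (8 in 2D, 26 in 3D),
configurable. Z-stacks can be filtered volumetrically (default) or
slice-wise; both are provided because either reading of the original
workflow is defensible.

**Limitation.** For tubes thinner than ~2 px radius the multi-scale maximum
inherits a one-voxel halo from the coarser scales, which caps the
achievable Dice against a sharp geometric truth mask at roughly 0.8 for the
thinnest vessels; thicker vessels score 0.84–0.87. This is a property of
the enhancement filter, not of the threshold estimation.

## Microglia segmentation

**Soma detection.** The IBA1-like channel has up to three intensity
populations — background, processes, somata. Two-class Otsu on such sparse
fields always cuts at the background/signal boundary (the signal mass is
small, so the split that separates it from background dominates the
between-class variance), which merges proximal process stubs into somata.
The default soma threshold is therefore taken from the three-class Otsu
split: of its two cuts, the one spanning the widest inter-class mean gap.
With a process class present this is the upper cut (process/soma boundary);
in process-free fields, where the three-class split subdivides the soma
class itself, it is the lower cut (background/soma boundary). Plain Otsu
and Triangle remain available via `threshold_method`. Components pass a
strict > 60 µm² size filter, evaluated on the xy-projected footprint in 3D
(thin anisotropic stacks make projected area the stable quantity).

**Single cells.** Cell masks come from a second, lower threshold — Triangle
by default in both modes — because branching analysis needs the dim distal
processes that sit near the histogram foot and are cut by any Otsu variant.
Each foreground component is assigned to the soma it contains; components
holding ≥ 2 somata are flagged touching and excluded from single-cell
morphometrics; the 2D human mode additionally drops components of
≤ 2000 pixels. All size comparisons are strict inequalities.

**IgG.** Leakage is pixels strictly above intensity 25 (8-bit scale),
components ≤ 5 µm² removed, reported as percent of the field. The fixed
threshold presumes 8-bit-normalized input.

## Morphometrics

Cell masks are thinned to one-voxel skeletons (topology-preserving
3D-capable thinning). The skeleton graph has voxel nodes and
full-connectivity edges weighted by the Euclidean distance between voxel
centers *in µm*, so anisotropic z-spacing is handled exactly. Terminal
spurs attached to a junction and shorter than 1 µm (configurable) are
pruned as thinning artifacts. Adjacent junction voxels are merged into a
single branch point. Branches are maximal paths between nodes of degree
≠ 2, measured between topological nodes (the 3DMorph convention), not
root-to-leaf.

For feature assembly, skeleton voxels inside the soma mask are excluded:
the soma core of a skeleton is not a process, and this makes a soma-only
cell score zero endpoints and zero branch length, as it should. Nodes where
a branch exits the soma terminate branches without counting as endpoints.

The convex hull is computed over the *corner points* of every cell voxel
(centers ± half a voxel per axis) rather than bare centers: only then does
a filled convex solid score a ramification index of exactly 1 and the index
stay in (0, 1] by construction (the center-based hull of a plus-shaped
pentomino has area 2 against a cell area of 5). The ramification index is
cell volume (area in 2D) divided by hull volume — the solidity; 2D mode
computes area-based analogues of all eight features so both modes share one
schema: soma size, endpoints, branch points, max branch length, total
branch length, cell size, hull size, ramification index.

**Accuracy.** On rendered trees the skeleton recovers endpoint counts
exactly when branches are separated by more than ~2 voxels; maximum branch
length carries a small negative bias (thinning erodes tips by roughly the
branch radius), with median relative error ~3% and worst cases near 15%
when branches run close together.

## Vascular-associated microglia

A cell is a VAM when the minimum Euclidean distance from its soma voxels to
the vessel mask — read off the anisotropically sampled distance transform —
is at most the attachment distance. The default is one voxel diagonal,
i.e. direct contact up to grid discretization; it is exposed as
`--attach-distance` and logged in the manifest. Soma contact (not process
contact) defines attachment in both species modes. Densities divide counts
by the xy footprint area in mm²; 3D stacks use their projected area.

## Clustering

Features are z-scored per column (population SD; constant columns are an
error). Ward-linkage agglomerative clustering on Euclidean distances is cut
at k = 4 by default — the empirically observed number of morphology states
— but the full linkage tree and silhouette scores for k = 2…8 are always
emitted, since the morphological transition is continuous and no selection
criterion is canonical. UMAP (n_neighbors 15, min_dist 0.1, fixed seed 42)
provides the 2D visualization; all three parameters land in the run
manifest. Clustering can be run pooled or per region.

## Statistics

- Welch's t with Welch–Satterthwaite degrees of freedom, two-tailed.
  Identical constant groups return t = 0, p = 1 rather than an error.
- Two-way ANOVA uses partial (Type-III-style) sums of squares with
  sum-to-zero factor coding, so unbalanced layouts are valid. Post hoc
  comparisons (all pairwise cell comparisons by default; marginal
  comparisons optional) use t statistics on the pooled residual mean square
  with Holm–Šídák step-down adjustment:
  adjusted_(i) = max-so-far of 1 − (1 − p_(i))^(m − i + 1), capped at 1.
- Spearman ρ uses average ranks; p-values use the t-approximation for
  n > 10 and exact permutation enumeration for n ≤ 10 (the tie structure is
  preserved by permuting the observed ranks).
- 2^−ΔΔCt: replicate Ct values are averaged per sample and gene; ΔCt is
  target minus reference; ΔΔCt subtracts the control-group mean ΔCt; the
  fold change is 2^−ΔΔCt, so the control group averages 1 by construction.

Whether cells or donors are the unit of analysis is left to the caller:
tables carry both identifiers and can be aggregated per animal/donor before
testing.

## Synthetic data

The generator emulates confocal fields at the study's acquisition
geometries (presets for 1.25 × 1.25 × 1 µm³ stacks and 0.16 × 0.16 × 0.3
µm³ single-cell imaging; any 2D/3D shape and voxel size is accepted).
Geometry is generated in µm coordinates and rasterized with per-axis voxel
sizes. Intensities follow an 8-bit convention: background ~4, vessel tubes
peak 200 with a parabolic radial profile, somata 215 (center) to 170 (rim),
branches taper 45 → 30, leakage blobs peak 60–160 — somata deliberately
much brighter than processes, matching IBA1 contrast, so an automatic
threshold can isolate them.

- **Vessels** are smooth random curves entering at an in-plane border, with
  radii drawn from 2–3.5 µm; in 3D the centerline stays at least one radius
  + 2 µm away from the axial faces, as acquired stacks frame their vessels.
  Masks are the exact rendered support (distance to centerline ≤ radius).
- **Cells** are spheres (discs in 2D) with 3–5 gently curving branch
  polylines of 12–25 µm at angular separation; ground truth (branch arc
  lengths, leaf counts, soma geometry, hull) is defined on the generative
  graph and the noise-free rendered masks, not re-measured from noisy
  voxels. Each cell is independently vessel-attached with probability
  `vam_fraction` (binomial planting, so field-level VAM frequencies carry
  the sampling variance a real cohort would show); attached somata are
  centered within half a soma radius of the vessel surface, unattached
  somata keep a > 6 µm clearance.
- **Leakage** paints perivascular Gaussian blobs (within 12 µm of a vessel)
  until the above-threshold fraction reaches the target, with overshoot
  bounded by one blob; saturation warns and records the achieved fraction.
- **Noise** is Poisson shot noise plus Gaussian read noise (default σ = 5
  on the 8-bit scale), clipped to [0, 255]. The study does not describe its
  imaging noise; these defaults are conventions chosen to be visually
  plausible for confocal data, and all are exposed.
- **Reproducibility**: every field derives its RNG streams from
  (master seed, field index), so datasets are bit-reproducible.

What the generator does *not* emulate: optics beyond a mild Gaussian blur
(no PSF anisotropy), photobleaching, intensity inhomogeneity, densely
overlapping arbors, or real biological covariance between morphology
features. Passing recovery tests therefore demonstrate correctness of the
measurement chain under controlled conditions, not performance on real
tissue.

Morphology *archetype* sampling (for clustering validation) draws 8-feature
vectors from four regimes spanning the ramified → hypertrophic → bushy →
amoeboid continuum with 10% multiplicative log-normal noise; the regimes
differ several-fold in soma size, endpoints and ramification index, as the
observed clusters do.

## Problem sizes and determinism

Validation uses fields of 16–20 × 128–160 × 128–160 voxels with 6–8 cells
and 3 vessels, and 2D 192² fields for morphometric recovery — large enough
for every structure to fit with realistic spacing, small enough that the
full suite and the acceptance script each run in minutes on one CPU. The
pipeline is deterministic end-to-end under a fixed seed; the run manifest
records resolved parameters and SHA-256 digests of all outputs, and
re-running a manifest reproduces every table byte-for-byte.
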