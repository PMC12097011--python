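# Methods

This note documents the models, numerical choices, and limitations behind
`hepamorph`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## The imaging model

Whole-mount Nissl staining imaged in reflected bright field gives bright
lumens (veins, arteries, bile ducts, sinusoids) over darker, cell-dense
parenchyma; steatotic regions — vacuolated hepatocytes with interspersed
small dark cells — sit at an intermediate gray level. All geometry is
carried by `VoxelGrid`: a 3D array plus physical voxel spacing in µm
(voxel-centred, 0-based; the coordinate of index *i* is
`origin + i·spacing`). Physical measurements are taken on the 1 µm
isotropic grid; anisotropic inputs (e.g. 0.35 × 0.35 × 1 µm acquisitions)
are resampled first.

## Synthetic phantom

The phantom generator defines the study conditions for every test; its
defaults are fixed once and shared by the whole suite.

**Vein trees.** Rooted trees of straight tubular branches; child radius =
parent radius × `radius_ratio` (default 0.75), branches thinner than
`min_radius` (3 µm) are not emitted; a degenerate root below `min_radius`
is clamped *up* so the tree still produces testable output. Default root
radius 15 µm (≈30 µm central-vein diameter, realistic for mouse), three
branching generations. The central system occupies the low-x half-space
and the portal system (with artery and bile-duct companion tubes offset
12 µm from the portal surface) the high-x half — central veins drain the
lobule centre, portal tracts sit at the periphery — which also guarantees
the two thresholded lumen systems stay disconnected for seeded region
growing. Rasterization is voxel-centre-in-tube with flat end caps (a
zero-length branch is a sphere); no anti-aliasing, matching thresholded
real inputs. Cylinder and sphere volumes agree with πr²L and 4/3πr³
within 5 % at r ≥ 5 µm on the 1 µm grid.

**Sinusoids.** Uniform random nodes at `node_density` (default
55 000 mm⁻³, about one node per 26 µm cube, matching the real branching
scale) joined to their 3 nearest neighbours and bridged into a single
connected component, rasterized at 4 µm tube radius. A ~3-voxel rind
around vessels is kept sinusoid-free: physically the vein wall, and
numerically wide enough that a radius-1 median filter cannot fuse the
thresholded compartments.

**Steatosis.** Spherical droplets (radius uniform in 3–8 µm) are proposed
uniformly in a shell around the central-vein surface, extended by one
droplet radius on both sides of the surface and beyond the outermost band
edge so coverage has no edge deficit. A droplet is accepted with a
band-dependent probability. Because droplets overlap and the mask is
their union, accepting with the raw band probability would *not* give
that coverage; the acceptance probability for band *b* is calibrated as
`a_b = −ln(1 − p_b)/λ` where λ (`coverage_intensity`, default 3) is the
expected number of proposals covering a point, so the Boolean-model union
coverage `1 − exp(−λ a_b)` equals the programmed fraction `p_b`. Bands
programmed at saturation clamp `a_b` to 1 and reach coverage
`1 − e^{−λ} ≈ 0.95`. The default profile (0.68, 0.56, 0.30, 0.18) over
0–30–60–90–120 µm bands is recovered by the distance-band analysis within
±0.05 per band on a 192³ phantom with ≥2000 accepted droplets.

**Label composition.** One integer volume with codes 0 parenchyma,
1 central vein, 2 portal vein, 3 artery, 4 bile duct, 5 sinusoid,
6 steatosis; pairwise disjoint by construction. Steatosis overwrites
sinusoids (pericentral sinusoids are destroyed inside steatotic regions)
but never vessel lumens.

**Intensity.** Per-label means (parenchyma 80, lumens 190, steatosis 150
on an 8-bit scale) × a smooth multiplicative bias field + an additive
axial sinusoidal stripe (a deliberate 1-D simplification of periodic
sectioning artifacts) + Gaussian noise, clipped. The gray-level means are
free parameters of the generator, not calibrated to any published
measurement (none exist); what matters downstream is ordering and
contrast-to-noise. A single seeded `numpy` generator threads through all
stochastic steps: identical config + seed ⇒ bit-identical volumes.

The phantom does **not** model hexagonal lobule tiling, hemodynamics,
inflammatory cells, or anisotropic PSF blur; passing tests demonstrate
correctness of the measurement chain, not segmentation performance on
real acquisitions.

## Preprocessing

Order: bias → stripes → denoise/normalize → resample; each stage
skippable. Bias correction divides by a mass-normalized Gaussian estimate
(smoothed image / smoothed indicator, removing kernel-truncation bias at
the faces) and rescales to preserve the global mean; it is approximately
idempotent (<1 % RMS change on reapplication). Stripe removal models the
periodic artifact as a 1-D additive profile along the slice axis and
notches the detected (or given) frequency and its first harmonic from the
axis-averaged profile only, leaving in-slice content untouched; the
period can be auto-detected as the spectral argmax. Denoising is a median
filter; contrast normalization affinely maps the (p_low, p_high)
percentiles to [0, 1] with clipping. Resampling is trilinear for
grayscale and nearest-neighbour for labels (no label invention), output
shape `round(extent/target)` per axis.

## Vessel segmentation

Region growing is implemented as thresholding within [low, high] followed
by connected-component labelling (26-connectivity by default) and seed
assignment — exactly equivalent to breadth-first flood fill, and verified
against a BFS oracle property test. A component reachable from several
seeds takes the first seed in list order (documented tie-break). Seeds
are physical µm coordinates, so seed files stay valid across resampling.
Intensity windows are explicit configuration (interactive thresholding in
the original workflow); defaults are phantom-calibrated. Sinusoids are
the same threshold window minus the vessel mask, minus components below a
volume cutoff. Central-vs-portal classification uses the one anatomical
invariant available in Nissl contrast: portal veins run with artery and
bile duct. A branch is portal iff more than `companion_fraction_threshold`
(default 0.5) of its centreline points have companion voxels within
`search_radius_um` (default 40 µm). Arteries and bile ducts are not
distinguished from each other, and their segmentation itself is out of
scope (manual in the original workflow); the phantom provides them as
truth.

## Skeleton morphometry

3D thinning uses Lee-style topology-preserving skeletonization. Two
implementation guards: (1) masks touching the volume faces are
replicate-padded before thinning so structures cut by the field of view
do not retract inward; (2) a mask component whose skeleton vanishes
entirely (the thinning implementation erases objects with perfectly even
cross-sections, which have no unique centre plane) is restored as its
maximum-distance-transform voxel, preserving component counts.

The branch graph places nodes at skeleton voxels with 26-neighbour count
≠ 2; junction voxels form small adjacent clusters, which are merged into
single nodes (otherwise every junction fragments into spurious one-voxel
segments). Edges are maximal chains between clusters; isolated cycles
become self-edges anchored at a designated voxel. Terminal spurs shorter
than `prune_below_um` are removed and the graph re-simplified iteratively.
Arc length is the sum of voxel-centre Euclidean steps (no spline
smoothing); on analytic cylinders the skeleton length is within 10 % of
the true length, and tree total length is recovered within 10 % when
branch lengths dominate radii (junction overlap consumes roughly one
radius per joint, so stubby trees under-measure — a known, documented
bias).

Per-point radius is the Euclidean distance transform of the mask at the
skeleton point; mean diameter is the **arc-length-weighted** mean of
2·radius (uniform per-point averaging would over-weight densely sampled
junctions). Length density converts µm·µm⁻³ to m·mm⁻³ (×10³); volume
fraction and total volume are exact voxel counts × voxel volume. Group
comparison is the pooled-variance two-tailed Student's t (Welch available
behind a flag), reporting mean ± s.e.m.; zero variance with equal means
returns t = 0, p = 1, with unequal means it raises (statistic undefined).

## Steatosis classifier

A one-hidden-layer network (default 8 tanh units) on per-voxel features:
Gaussian-smoothed intensity and local standard deviation at each scale,
plus one local intensity range — 2·|scales|+1 features. A hidden layer is
required because steatosis occupies an *intermediate* gray band (brighter
than parenchyma, darker than lumens), which no linear boundary can
isolate. Training is full-batch gradient descent on the logistic loss
over annotated voxels only (codes 0 unlabeled / 1 target / 2 background,
mirroring sparse brush annotation); features are standardized on the
training split; an internal split (default 20 %) provides validation
curves of loss, accuracy, and IoU logged every 50 iterations. Training is
deterministic given the seed. Prediction thresholds the score (default
0.5), then optionally applies morphological closing and minimum-component
filtering. On a separable phantom (steatosis/parenchyma separation ≈8.75
noise sd) the classifier reaches ≥99 % held-out voxel accuracy; on the
full default phantom the predicted mask reaches IoU ≥ 0.85 against truth
at 5 % noise, and the full chain (features → train → predict → band
quantification) recovers the programmed band profile within ±0.07.

## Perivascular distance analysis

Distances are Euclidean from exterior voxel centres to the nearest
foreground voxel centre (≤ half-voxel bias versus the true surface,
below every tolerance used); interior voxels carry a sentinel and are
excluded from all accounting. Bands are half-open [lo, hi) and partition
the 0–max(edges) shell exactly; an optional exclude mask removes other
vessels' interiors from both region and steatotic volumes. Shells around
branches exclude the branch interior; for diameter-class stratification
each vessel voxel is assigned to the branch with the nearest centreline
point, same-class shells are unioned (never double-counted), and voxels
in shells of several classes go to the larger-diameter class.

## Per-component statistics

EqDiameter is exact, (6V/π)^(1/3). Length3d is the maximum Feret diameter
over the corners of the component's voxels (convex-hull vertices, then a
pairwise search; a single 1 µm voxel measures √3 ≈ 1.73 µm). Thickness3d
is twice the maximum interior distance-transform value. Perimeter — a 2-D
quantity listed for 3-D objects — is implemented as the 4-connected
boundary length per slice, summed along the slicing axis. Surface area
for the sphericity index Shape_VA3d = A³/36πV² uses exposed-face counting
with a 2/3 correction (face counting overestimates a smooth surface by
3/2 on average over orientations); a digitized sphere measures
Shape_VA3d ≈ 1.0, while voxelization pushes tiny components down to ≈0.2
for a single voxel — documented rather than clamped. Aggregates report
mean/min/max/median, sample variance (ddof 1), population skewness, and
**raw (non-excess) kurtosis** m₄/m₂²: under a single dominant outlier
among n components the raw kurtosis tends to (1+(n−1)³)/(n(n−1)) ≈ n,
the behaviour observed in reference per-object tables; excess kurtosis
would not reproduce it. A single component reports variance 0 and NaN
skewness/kurtosis.

## Pipeline

Stage order: input → preprocess → vessels → morphometry → steatosis →
spatial → labelstats. A stage with missing inputs aborts naming the
stage and the missing input. With phantom input, region-growing seeds
are derived from the ground-truth tree roots and classifier annotations
are sampled from truth labels (5 % of each class); with file input the
user supplies a seeds file and an annotation volume. Vessel lumens are
always removed from the predicted steatosis mask. Every run writes a
manifest with the seed, a config hash, the stage list, and wall times;
reruns with identical config and seed are byte-identical. The library
API is the primary interface; the `hepamorph` console script is a thin
veneer over it.

## Problem sizes and known limitations

The suite runs on 48³–192³ phantoms (the band-recovery condition uses
192³ with ≥2000 droplets; the classifier evaluation uses two 128³
phantoms), chosen so that full-precision statistics are computed at desk
scale. The 90–120 µm band of small demo volumes is truncated by the
field of view and reported as absent rather than extrapolated.
Morphometric absolute values from real terabyte-scale acquisitions are
not reproduced — only the measurement definitions, their analytic
calibrations, and the direction of the fibrosis contrast (a "fibrotic"
phantom with thinner, more numerous central-vein branches yields lower
mean diameter and higher length density than a "control" phantom) are
asserted. Amira/Imaris-compatible bit-exactness of Length3d, Thickness3d,
Perimeter, and Shape_VA3d is not claimed; the definitions above are the
stated, tested contract.
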