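# Methods

`pllptools` quantifies size control in migrating epithelial cell clusters —
the motivating system is the zebrafish posterior lateral line primordium
(pLLP), a cohesive group of ~100 progenitors with membrane-localized GFP —
from 3D confocal stacks.  This note records the models, conventions, and
numerical choices behind each stage, and what the synthetic benchmark does
and does not establish.

## Synthetic ground truth

Because per-embryo image data for this kind of study are rarely deposited,
the package ships a generator that emulates the imaging substrate with an
exact digital ground truth, so every stage can be scored against known
answers.

**Geometry.**  Cells are the Voronoi regions of `n_cells` centers inside an
elongated ellipsoid (long axis = anteroposterior).  Centers are placed by
rejection sampling with a minimum separation of 0.6 × the equivalent-sphere
cell diameter — a packing fraction comfortably below the random-sequential-
addition jamming limit, so placement succeeds at any density — followed by
two Lloyd relaxation steps (move each center to its region's centroid),
which gives the near-centroidal, convex-polyhedral cell shapes typical of
packed epithelia.  Placement stalls (5000 consecutive rejections) raise an
error reporting the achieved count.

**Intensity model.**  Outside the ellipsoid the image is
`background_level`; inside, `interior_level` plus a Gaussian membrane ridge
peaking at `membrane_peak` on every inter-cell and cell–exterior boundary
(σ = half the nominal `membrane_width`, truncated at one membrane width so
interiors are exactly quiet).  The image is then blurred with an
anisotropic Gaussian PSF and corrupted by additive Gaussian noise.  Poisson
shot noise, photobleaching, depth-dependent attenuation, cell divisions
during acquisition, and the flat-to-columnar cell-shape gradient of the
real primordium are *not* modeled; recovery results on this benchmark
demonstrate correctness of the algorithms under their stated assumptions,
not performance on arbitrary real acquisitions.

**Defaults** (chosen once, as plausible values for a confocal stack of a
~100-cell cluster): grid 32 × 64 × 128 voxels at 1.0 × 0.5 × 0.5 µm (z, y,
x); ellipsoid semi-axes 12 × 13 × 28 µm (equivalent cell diameter ≈ 7 µm);
membrane width 1 µm; intensity levels 10 / 20 / 100 (background / interior
/ membrane peak); PSF σ = 0.8 / 0.3 / 0.3 µm; noise σ = 10 (“moderate”:
12.5% of the membrane contrast); EdU fraction 0.3; migration speed
60 µm/hr sampled every 10 min.

**Seeding.**  One integer seed drives a `SeedSequence` hierarchy with
independent sub-streams for placement, image noise, the EdU channel, and
per-frame time-lapse noise, so e.g. toggling the EdU channel never changes
the geometry, and identical specs give bit-identical outputs.

**EdU channel.**  Each cell is independently positive with probability
`edu_fraction`; positive cells carry a Gaussian nuclear blob (σ = 0.25 cell
diameters) at their center, followed by the same PSF/noise model.

**Time-lapse.**  A noise-free template is rendered with the cluster at the
left of the field and translated along +x by `speed × frame_interval` per
frame (linear interpolation for subvoxel shifts); each frame receives
independent noise.  Series that would carry the cluster out of the field
are rejected.

## Membrane enhancement

A fluorescent membrane is locally a bright plane, so the smallest
eigenvalue μ₁ of the Gaussian-smoothed intensity Hessian is strongly
negative on membranes and near zero elsewhere.  All derivatives are taken
in physical units (per-axis voxel sigmas, second derivatives scaled by the
spacing products), which is what makes coarse z sampling work without
resampling.  The image mean is subtracted before differentiation because
truncated derivative kernels have a small nonzero DC response that would
otherwise leak a constant offset into the Hessian.

The denoising step is divergence-form anisotropic diffusion
∂u/∂t = div(D ∇u).  At each voxel, D has eigenvalue
`alpha + (1 − alpha)·exp(−(μ₁/λ)²)` along the eigenvector of μ₁ (the
membrane normal) and 1 in the two in-plane directions: smoothing across the
membrane is suppressed where plane evidence is strong, free elsewhere.  The
contrast scale λ defaults to a robust scale (1.4826 × MAD) of μ₁ over the
volume.  D is computed once from the input and held fixed over the
explicit iterations — a linear scheme; at the modest iteration counts used
here (default 10) it is indistinguishable in effect from updating the
tensor each step, and several-fold cheaper.

The explicit update uses staggered face fluxes (exact two-point normal
differences on faces, averaged tangential differences and tensor entries)
with zero-flux boundaries, so the voxel sum telescopes and total intensity
is conserved to machine round-off.  The time step defaults to 0.9 × the
isotropic stability bound `1/(2 Σ 1/h_k²)`; larger values are rejected.
Because the mixed-derivative flux terms are not a nonnegative stencil, the
discrete extremum principle is not guaranteed in exact arithmetic, but in
practice the output range stays inside the input range (the test suite
checks this with a 10⁻⁶-of-range tolerance).

Default Hessian scale: 1.2 × the membrane width.  This was calibrated on
the synthetic fixtures: at 1.5 × the membrane width the thin interiors of
cells at the cluster surface are washed out and their basins merge into
the background, biasing counts low by ~5 cells per 100.

## Segmentation

The watershed landscape is the *negated* indicator, so membranes become
ridges and cell interiors catchment basins — flooding the eigenvalue image
directly would segment the membranes, not the cells.  Regional minima
shallower than `h` are suppressed by grayscale reconstruction by erosion of
(landscape + h) over the landscape, under the same connectivity used for
flooding (default 26; both 26 and 6 supported).  `h` defaults to 3 × the
robust noise scale (1.4826 × MAD) of the landscape, adapting to the
intensity scale of the input; counts are insensitive to `h` over roughly
[0.3, 1.2] indicator units on the default benchmark.  Flooding uses
`skimage.segmentation.watershed`, which is deterministic for fixed input;
plateau tie-breaking is therefore implementation-defined, and the test
suite's independent priority-flood reference is compared on tie-free
landscapes where no tie policy can matter.

Fragments smaller than `min_volume` (default 10% of the expected cell
volume) are deleted and the surviving segments re-flood the whole grid as
seeds on the same suppressed landscape; the labeled voxel set is preserved
exactly and labels are renumbered contiguously.  If every segment is
undersized, the largest is kept as the sole seed rather than returning an
empty labeling.

## Primordium mask and counting

The whole-cluster mask is computed from the *raw* (not diffusion-enhanced)
intensity: Gaussian smoothing at half a cell diameter (enough to bridge
the dark interiors between bright membranes so the cluster thresholds as
one solid region, small enough to preserve the outline), followed by Otsu's
threshold — the split of a 256-bin histogram minimizing within-class
variance, returned as the upper edge of the low class — hole filling, and
retention of the largest 26-connected component (a deposited organ in the
field must not join the mask).

A segment is counted as a cell of the cluster iff **strictly more than
75%** of its volume lies inside the mask; a segment at exactly the
threshold is excluded.  The full per-segment fraction table is returned
for audit.  This rule is monotone in the mask: enlarging the mask can only
add cells.

## EdU index and regional split

Counted cells are scored by their mean nuclear-channel intensity.  Otsu's
threshold on the per-cell mean distribution separates positive from
negative cells when the distribution is genuinely bimodal (class-mean gap
> 4 × the pooled within-class spread).  When it is unimodal — every cell
positive, or none — any split would be spurious, so the cells are instead
compared with the image background: positive iff the mean exceeds the
background mean by 6 × the sampling noise of one cell mean (background SD /
√(median cell size); zero-background convention when no unlabeled voxels
exist).  At least two counted cells are required.

The leading/trailing partition runs along the mask's principal axis
(second-moment analysis), oriented toward +x by default (the migration
direction in the synthetic data; flippable per sample).  The leading
region is by default the front **one third** of the principal-axis extent.
This boundary is a convention, not a measurement — the biological
distinction (the rosette-free zone) has no fixed numeric location — so
results carry a sensitivity report: the regional indices recomputed with
the boundary shifted by ±10% of the extent.

Expression-domain extents use the same positivity machinery on in-mask
voxel values; `mode="length"` reports the span of positive voxels along
the principal axis relative to the mask extent, `mode="area"` the positive
voxel fraction.

## Migration kinetics

Each time-lapse frame collapses to a 1D anteroposterior profile by maximum
intensity projection over the transverse axes; stacked profiles form the
kymograph.  Per frame, the front is the most distal descending crossing of
the half-maximum level — halfway between the profile baseline (10th
percentile) and its robust maximum (99th percentile, guarding hot pixels)
— on a median-smoothed (5-sample) profile, with subpixel linear
interpolation.  The baseline term matters because a MIP over thousands of
transverse voxels raises the background floor at realistic noise levels.
Speed is the ordinary least-squares slope of front position (µm) against
time (hr); a frame with no contained crossing aborts with the frame index.
This automated rule replaces whatever manual readout a bench scientist
would use on a kymograph; it is auditable but not a replication of any
particular manual protocol.

## Group statistics

Conventions follow common practice for per-embryo measurements: Welch's
unequal-variance t-test (via `scipy.stats.ttest_ind(equal_var=False)`,
with the convention t = 0, p = 1 for two zero-variance groups with equal
means); effect sizes as differences of group *means* in percent of the
reference-group mean; per-value normalization by the reference mean;
boxplots with linear-interpolation quartiles and 1.5·IQR whiskers;
two-sided p-values; no multiple-testing correction (raw pairwise values).

## Problem sizes and what the tests show

The default benchmark volume is 32 × 64 × 128 voxels with 100 cells — large
enough that cells are resolved by ~14 voxels across in-plane and ~7 in z,
small enough that a full pipeline run takes about a second, so recovery
statistics over tens of seeds run in minutes.  Recovery results at these
sizes (counts within ±5 of truth at moderate noise, EdU index within 0.03
of the generating fraction, speed within 5% at 20% noise) validate the
algorithm chain end-to-end against exact ground truth; they do not
quantify performance on real stacks, where PSF mismatch, shot noise, and
unmodeled shape gradients will dominate the error budget.

## Known limitations

- The leading/trailing boundary and the EdU positivity fallback are
  conventions; both are surfaced in the outputs (sensitivity report,
  threshold value) rather than hidden.
- The generator's Voronoi geometry has no cell-shape gradient and no
  rosettes; segmentation difficulty in the trailing region of real
  primordia is likely understated.
- Anatomical staging ("mid-migration") is user-supplied metadata; the
  package records it but cannot compute it from an image.
- The diffusion scheme's extremum principle is empirical, not proven, for
  the full tensor stencil.
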