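# Methods

## Estimation model

A subject's intracranial segmentation is represented by its area
profile: cross-sectional areas A(x) (mm²) at 1 mm slice positions along
one anatomical axis. Profiles must have contiguous positive support —
a real vault has no interior empty slices — and integrate (slice sum ×
slice thickness) to the segmentation volume exactly.

Sparse sampling keeps every *n*-th slice. The first sampled slice is
restricted to lie within one spacing of the outermost positive-area
slice on a fixed starting side (anterior for coronal, superior for
transversal, the low-index end for sagittal), so spacing *n* admits
exactly *n* subsamples, indexed by offset k = 0 … n−1, which together
partition the support. For the linear and spline interpolants a zero
area is appended one slice beyond each end of the support — the first
empty slice, where the vault has ended — so the interpolant reaches the
vault borders. The rectangle-rule estimator uses no pads (they would add
nothing to a sum).

Estimators:

* constant: Σ areas × n.
* linear: trapezoidal rule over the padded points with their actual,
  generally unequal, end spacings.
* spline: the not-a-knot cubic interpolating spline through the padded
  points, integrated exactly via its piecewise-polynomial
  antiderivative. With three points the not-a-knot conditions
  degenerate and the unique parabola is used; with two, the straight
  line (scipy's `CubicSpline` implements exactly this degradation).
  Spline values are *not* clamped at zero: negative lobes near the pads
  integrate as-is, which is what a plain interpolate-and-integrate
  pipeline produces; a warning is logged when a segment dips below
  zero, and nonpositive totals are flagged.

At spacing 1 the constant and padded-linear estimators reproduce the
slice-sum volume exactly (the trapezoid sum telescopes); this exactness
is a standing regression test.

## Validity evaluation

With *m* subjects and spacing *n* there are *n*ᵐ ways to choose one
estimate per subject. The evaluation draws per-subject offsets
independently and uniformly (with replacement across the combination
space), 2000 combinations per setting by default, and scores each
combination against the true volumes with:

* ICC(A,1) — two-way ANOVA with subjects as targets and
  {truth, estimate} as two raters; single measures, absolute agreement:
  (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE)), k = 2. The two-way
  random- and mixed-effects formulations share this point estimate, so
  both flags are accepted. Degenerate (zero-variance) input raises
  rather than returning 1: silent perfection masks bugs.
* Pearson's r.
* Generalized Jaccard index Σ min(xᵢ,yᵢ)/Σ max(xᵢ,yᵢ) (positive
  volumes only).
* Signed percentage errors 100·(V̂ − V)/V per member estimate, pooled
  over all members of all combinations (percentiles of the pooled
  errors, not of per-combination maxima, to limit the influence of
  extremes).

Percentile curves report the 5th/25th/50th/75th/95th percentiles
(linear interpolation between order statistics) per (spacing,
orientation, method); metric means are stored alongside. Within one
(spacing, orientation) the same combinations are reused for all three
methods, so method contrasts share sampling noise; each setting draws
its combinations from an RNG substream keyed by (seed, orientation,
spacing) and is therefore independently reproducible. Degenerate metric
values become NaN with a logged warning, never silently dropped.

The constant-vs-spline contrast uses each subject's mean absolute
percentage error over all *n* offsets and a two-sided paired t-test
(closed-form statistic; significance threshold 0.05), reporting the
mean difference (constant − spline, positive = spline better) with a
95 % t-interval.

## Phantom generator

The generator emulates the population structure of a 62-subject
memory-clinic sample: a fixed roster of 39 female and 23 male subjects;
per-gender ICV targets drawn from normals (female 1 416 955 ± 91 678,
male 1 658 268 ± 115 535 mm³) truncated at ±4 SD (truncation this far
out leaves the moments essentially unchanged while excluding
nonphysical draws); sagittal extents from N(136, 5²) slices, with
coronal and transversal extents at fixed ratios 1.25 and 0.95 of the
sagittal extent (only sagittal slice counts are empirically
constrained; the ratios approximate adult head proportions).

Each orientation's profile is a unimodal dome

    A(u) ∝ (1 − |u|^p)^(1/q),  u ∈ [−1, 1] at slice centres,

modulated multiplicatively by one to three low-frequency sinusoids
(0.5–2.5 cycles across the support, random phases) with total relative
amplitude `irregularity`, floored at zero, then rescaled so the slice
sum equals the subject's target volume exactly — hence all three
orientations share one total volume, which serves as ground truth.
Per-subject RNG substreams (seed, subject index) make cohorts
element-wise reproducible.

Defaults were calibrated once, before freezing, so that the phantom
cohort's validity curves match the shape and level of curves observed
for real manually segmented vaults: p = 2, q = 1 — exactly the
cross-sectional area law of an ellipsoidal vault, with finite edge
slopes — and irregularity 0.03 (sagittal, coronal) / 0.25
(transversal). Steeper-edged shape families (e.g. the elliptical law
p = q = 2, whose edges have square-root singularities) make every
interpolant, especially the spline, degrade far faster with spacing
than real vaults do; the calibrated defaults reproduce the
characteristic real-data pattern: near-perfect validity for every
method at spacings ≤ 15 mm, a growing spline advantage on smooth
sagittal/coronal profiles at coarse spacings, progressive trapezoid
underestimation bias, and a collapse of the spline advantage on the
irregular transversal profiles.

`profile_to_mask` voxelizes a sagittal profile into stacked elliptical
cross-sections (anterior–posterior to superior–inferior aspect ratio
1.3 by default), ranking voxels by elliptical radius and keeping
exactly `round(area)` per slice, so per-slice areas match to half a
voxel; it exists to exercise mask-based code paths, not to mimic skull
anatomy.

What the phantoms deliberately do not model: rater variability (real
re-segmentations add variance that lowers ICC below the spacing-only
values computed here), head tilt, anatomically detailed vault shapes
(skull base, sinuses), or any intensity-level segmentation difficulty.
Passing validity targets on phantoms therefore demonstrates the
machinery and the spacing-driven component of validity, not performance
on any particular scanner's data.

## Preprocessing module

The intensity-conditioning chain mirrors common practice for preparing
scans for manual tracing and is optional for estimation (it conditions
display data, not areas): per-scan robust mean over the central 80 % of
the representable tonal range [0, B−1] (B = 4096 for 12-bit data;
taking the band over the representable range rather than per-image
min–max keeps the band comparable across scans), additive brightness
matching to the cohort grand mean iterated ≤ 20 times to a 0.5-unit
tolerance (a single shift is inexact because clipping and band
membership change with the shift; whether such matching should be
additive or multiplicative is not standardized — additive is the
plainest reading and is what is implemented), 10 %-per-tail contrast
stretch, gamma correction y = B(x/B)^γ with γ = 0.8 (for γ < 1 values
just below the ceiling can exceed B−1 by under one unit and are clipped
back), and trilinear resampling to 1 mm isotropic voxels with masks
thresholded at 0.5.

## Numerical choices and edge cases

* Positions are slice centres at i × voxel_size, 0-based.
* Spacing is counted in slices; with the standard 1 mm resampling this
  coincides with mm.
* Whether zero pads belong at the last vault slice or one beyond is a
  genuine modeling fork; one-beyond (the first empty slice) is used,
  matching the reading that pads mark where the vault *has ended*.
* The sagittal offset starting side is a convention; reversing a
  profile permutes the offset estimates but leaves the multiset
  unchanged (asserted in tests), so metric distributions do not depend
  on it.
* Non-contiguous profile support, empty masks, anisotropic voxel grids,
  zero-variance ICC input, nonpositive Jaccard volumes and unknown
  orientation/method names all raise immediately with named-argument
  error messages.
* Monte-Carlo size 2000 matches the default reporting convention; the
  acceptance script and tests use the default cohort (62 subjects) and
  probe spacings 10, 24 and 50 mm, which keeps a full recomputation in
  the tens of seconds on one CPU.

## Known limitations

* The ICC here quantifies agreement between estimates and the *same*
  segmentations they were subsampled from; all variance is
  spacing-induced. Real applications add rater and scanner variance.
* Phantom realism is a modeling choice constrained only by volume and
  slice-count statistics; absolute validity levels at coarse spacings
  depend on the assumed profile smoothness.
* The spline estimator can return nonpositive values for pathological
  subsamples (flagged, not suppressed).
* Transversal phantom irregularity is a single amplitude knob; it does
  not reproduce the specific bimodal structures real axial profiles
  can show near the skull base.
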