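# Methods

`tractgap` quantifies three processing-step errors that arise when distances
between DBS electrode contacts and fiber tracts from probabilistic
tractography are used for targeting decisions: (1) the choice of the
binarization threshold for tract probability maps, (2) manual distance reading
on the contact's axial slice versus automated 3D distance maps, and (3)
normalization into a standard space. Because the clinical imaging behind such
analyses cannot be redistributed, the package ships a phantom generator that
reproduces the statistical structure those analyses rely on; every stage is
validated on phantoms.

## Coordinate model

All volumes are `Volume3D`: a 3D scalar grid plus a 4x4 voxel-to-world affine
in RAS+ mm (the NIfTI convention). Distances are always computed in world mm,
so anisotropic grids need no special handling. Voxel indices are 0-based and
refer to voxel centers; the "axial slice" of a point is the set of voxels
sharing its third (k) index. `nearest_voxel` rounds half-integer fractions
toward the lower index — an arbitrary but fixed tie-break chosen so results
are platform-independent.

## Robust-range thresholding

Streamline-count images are heavy-tailed: the 2nd–98th percentile "robust
range" (rmin, rmax) sits far below the global maximum, so meaningful
binarization cutoffs are *percentages of the robust range* well above 100%.
The cutoff at p% is `rmin + (p/100)(rmax − rmin)`; for the typical rmin = 0
this is p% of rmax. Percentiles use linear interpolation over **all** voxels,
zeros included; because binarization tools differ on whether zeros enter the
histogram, a `robust_range_nonzero_only` flag provides the other convention.
The comparison is `>=` (voxels exactly at the cutoff are kept). Masks are
nested by construction: the cutoff is affine-increasing in p. Note that this
is the plain percentile definition; the iterative-histogram robust range some
FSL tools compute internally is deliberately not replicated.

Threshold selection in practice is visual — the threshold giving the best
separation of the crossing (c-DRTT) from the non-decussating (nd-DRTT) bundle
on the whole brain. The package replaces this with an explicit proxy: among
candidates at which all four masks (2 tracts x 2 hemispheres) are non-empty,
pick the one minimizing the mean per-hemisphere Dice overlap between c- and
nd-masks; ties resolve to the lowest percentage, and an empty feasible set
falls back to the lowest candidate, flagged infeasible. This proxy is a
design decision, not a validated model of human raters; it exists to make the
selection reproducible and testable.

## Distance measurement

The automated path computes an exact Euclidean distance transform of the
binarized tract (scipy's exact EDT with per-axis sampling = voxel spacing, so
anisotropy is honored) and samples it at each contact's nearest voxel.
Nearest-neighbor sampling mirrors a per-coordinate export from a distance
image; the sampling error is bounded by half the voxel diagonal (1.73 mm at
2 mm isotropic), and a trilinear option exists for sensitivity analysis. An
independent brute-force oracle (minimum over mask voxel centers, no
precomputation) verifies the transform in the tests.

The manual technique is emulated by restricting the mask to the contact's
axial slice: if no tract voxel lies on that slice the distance is *not
measurable* (the mechanism that removes measurements from cohort
bookkeeping); otherwise the reported value is the Euclidean distance from the
pole coordinate to the nearest in-slice mask voxel center. The pole's true 3D
coordinate is used (not its in-plane projection), so a manual reading can
never undercut the true 3D shortest distance — the axial-dominance property
the tests quantify; a 2D projected variant is available as `in_plane=True`.
All techniques measure to voxel centers, not mask surfaces, so comparisons
between them are internally coherent. An optional zero-mean uniform jitter
(default 0) crudely emulates human reading error; it is an emulation knob,
not a rater model.

If an automated distance exceeds 10 mm at the working threshold (strict
`>`), the tract is re-binarized exactly one candidate step lower and
re-measured once; the step is per tract and recorded in the measurement's
provenance (`p_initial`, `p_final`, `stepped_down`). An empty mask at the
working threshold triggers the same single step; if none is available the
record is flagged by a NaN automated distance.

## Normalization error

Normalization is modelled as a 4x4 affine plus an optional smooth residual
field: component i of the displacement is
`sum_j (A[j,i]/3) sin(2*pi*x_j/lambda + phi[j,i])` with per-axis amplitudes
`A[j,i] ~ U(0, a)` and common wavelength lambda. The 1/3 normalization bounds
any displacement by `sqrt(3)*a` mm. The error protocol is scalar, mirroring
how native and normalized measurements are actually compared: `d_native` is
the tip-to-red-nucleus distance in native space, `d_norm` the distance from
the transformed tip to the atlas landmark, and the error is
`|d_norm − d_native|` — a difference of distances, not a point displacement.
Rigid transforms with a correctly placed atlas landmark therefore give zero
error exactly, and a pure isotropic scale s gives `|s − 1| * d_native`.
Errors above a cutoff (default 5 mm, exposed as a flag) are excluded as
assumed coordinate misrepresentation; the cutoff is a stand-in for a
subjective judgement and any value between the plausible retained maximum
(~2.3 mm) and a gross failure (~6 mm) partitions identically.

## The phantom generator

The generator's defaults define the study conditions; they are fixed, not
tuning knobs.

* **Grid**: 96^3 voxels at 2.0 mm isotropic (the DTI resolution typical of
  this application), world-centered.
* **Tracts**: per hemisphere, a c-DRTT and an nd-DRTT centerline (piecewise
  linear, 4 control points) ascending from the cerebellar to the thalamic
  end; lateral separation shrinks from ~12 mm to ~3 mm superiorly, so the
  threshold choice genuinely changes their discriminability. Intensity at
  distance r from the centerline is `round(5000 * exp(−r²/(2*sigma²)))` with
  sigma = 3 mm and peak 5000 (the conventional per-voxel sample count);
  values below 1 are zero. The true transverse profile of streamline-count
  images is not documented, so any monotone decay would do; the Gaussian is
  chosen for analytic testability.
* **Background noise**: 5% of zero voxels receive counts uniform in
  {1, ..., 50}. This keeps >= 90% of voxels zero (heavy tail) while placing
  the 98th percentile in the noise floor, far below the peak — exactly the
  regime in which 400–1000% robust-range thresholds are meaningful.
* **Leads**: one 4-contact lead per hemisphere, 2 mm center-to-center
  (conventional quadripolar geometry; 8-contact directional leads are one
  config change), aimed at the crossing tract's thalamic segment with 0–8 mm
  seeded lateral offset and a small random tilt.
* **Landmark**: a red-nucleus-like point midway between the two bundles, per
  hemisphere, jittered per patient; the atlas copy is the true transform's
  image of it (plus an optional placement offset, default 0).
* **Normalization**: per patient a small rigid rotation (±3°), isotropic
  scale U(0.96, 1.04) and translation (±5 mm), plus a residual field of
  amplitude 1 mm, wavelength 50 mm. `n_misnormalized` patients (default 1 of
  10) have their *applied* transform corrupted by an 8–25 mm translation
  while the atlas landmark was placed with the true transform — emulating
  coordinate misrepresentation after a failed normalization, which the
  outlier exclusion should catch.
* **Determinism**: every patient consumes an RNG stream keyed by (master
  seed, patient index), so growing the cohort never perturbs existing
  patients; rerunning a fixed (config, seed) reproduces every artifact byte
  for byte.

The default cohort is 10 patients (the size at which threshold sensitivity is
reported per-contact), configurable upward.

### What the phantom does and does not show

The phantom reproduces heavy-tailed count histograms, converging bundles,
anisotropy-safe geometry and failed-normalization outliers, so passing tests
demonstrate the *mechanics* of the pipeline: exactness of the distance
transform, nestedness/monotonicity across thresholds, the axial-restriction
penalty, the bookkeeping of unmeasurable readings, and the transform algebra
of the landmark protocol. It does not model real tractography (no diffusion
signal, no streamline propagation, no anatomy), inter-rater variability, or
registration of actual images; cohort-level error magnitudes from clinical
imaging are therefore not reproduced quantitatively, and phantom summary
statistics should be read as scaled-down analogues, not predictions.

## Numerical choices and degenerate inputs

* Distance-transform equality with the brute-force oracle is asserted to
  1e-6 mm; coordinate round-trips to 1e-9.
* A constant volume has a degenerate robust range (rmin = rmax); any
  percentage then yields the full mask (>= comparison), which is the least
  surprising continuation.
* Empty masks are legal values (flagged) everywhere except distance-map
  construction, which raises; the measurement stage converts that into a
  one-step threshold relaxation or a flagged record.
* Sample SD uses the n−1 denominator, with SD = 0 for singletons.
* Manual-vs-auto differences are reported as absolute values; with jitter 0
  they coincide with signed differences because of axial dominance.
* Threshold-sensitivity spreads (max − min of the automated distance across
  realized thresholds) use only thresholds with non-empty masks; groups with
  fewer than two realized thresholds are reported unassessable and excluded
  from the cohort summary.

## Known limitations

* The Dice-minimizing threshold selection and the 5 mm exclusion cutoff are
  explicit stand-ins for judgements that are subjective in practice.
* The manual emulation measures to voxel centers on the true slice; human
  raters judge tract edges on interpolated displays, so the emulated
  manual-vs-auto differences are conservative.
* The sinusoidal residual field is smooth and stationary; real registration
  error concentrates at anatomical boundaries.
* One landmark measurement per patient (left-hemisphere tip) is summarized;
  bilateral protocols would double n without changing the machinery.
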