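# Methods

This note documents the models and numerical choices behind `disconnmap`:
what is computed, under which assumptions, and what the synthetic validation
does and does not demonstrate.

## Damage prediction

All computation happens in world millimetres (RAS+); voxel indices appear
only when points are binned into a volume. A world point falls "in" a voxel
when the inverse affine maps it within half a voxel of that voxel's center
(nearest-integer rounding; half-integer ties round toward +∞ per axis).
Points falling outside the grid are silently ignored — normative tractograms
routinely overshoot a mask's field of view.

**Selection.** A streamline is damaged (control rule) iff at least one of its
stored coordinates voxelizes into a lesion voxel. No segment interpolation is
performed between stored points: normative tractograms are densely sampled
(steps ≪ voxel size), so no voxel can be skipped; for coarse external data
`resample_streamline` can enforce a maximum step first. Patient-derived
tractograms additionally use an endpoint rule: a streamline whose first *or
last* point falls inside the lesion dilated by 2 mm is also damaged, because
tracking through pathological tissue often terminates just short of the
lesion border (a streamline has no canonical direction, so both ends are
tested). Dilation is Euclidean in millimetres, using the voxel spacings from
the affine, so anisotropic grids are handled; it is implemented via
`scipy.ndimage.distance_transform_edt` with mm sampling.

**Visitation maps** count *distinct* damaged streamlines per voxel — a
streamline contributes at most 1 to a voxel however many of its points land
there. Counting coordinates instead would inflate values by the sampling
density (~10–20× at typical step sizes) and make maps incomparable across
tractograms with different stepping.

**Aggregation.** The per-subject maps are summarized voxel-wise by the mean
(the prediction), the sample standard deviation (ddof = 1; the maps feed
second-level analyses across subjects) and the standard error sd/√N.

## Reliability and calibration

Pearson correlations are evaluated over an explicit brain mask (the package
deliberately ships no default brain mask — it must match the space of the
inputs), optionally intersected with a field-of-view mask and optionally
excluding the lesion voxels; the lesion area is selected by construction in
every database subject, so including it inflates reliability for large
lesions. Correlations are averaged on the Fisher-z scale after clamping to
±(1 − 1e−7), which keeps degenerate perfect correlations finite. A subject
whose masked map has zero variance has no defined correlation and is dropped
from the group average with a warning rather than aborting the analysis.
No smoothing is ever applied inside the reliability computations.

The **deviation-score** normalizes the patient-minus-prediction difference by
the predicted per-voxel deviation `s = sqrt(sd² + se²)` — the standard
deviation of (new observation − estimated mean) under independence. A config
switch (`deviation_scale="sd"`) preserves the plain-sd alternative. Voxels
with `s = 0` are 0/0 cases (no streamline ever visits them) and are excluded;
their count is logged. "Standard deviation from zero" is taken literally: the
score is the RMS of the normalized differences (second moment about zero,
not about their mean), so a perfectly calibrated uncertainty gives 1 and a
patient equal to the prediction gives 0. The score is linear in the actual
patient deviation.

The **lesion-size fit** uses the saturating three-parameter exponential
`r(V) = a − b·exp(−c·V)` (`c ≥ 0`), fitted by nonlinear least squares
(`scipy.optimize.curve_fit`) on the correlation scale, with adjusted
R² = 1 − (1−R²)(n−1)/(n−4). Initial values come from the data (plateau from
the largest-V quartile, drop from the smallest); non-convergence returns the
best-found parameters flagged `converged=False`.

## Group inference

The two-group comparison uses the voxel-wise pooled-variance two-sample t
statistic, one-sided (deficit > no-deficit; an inverse relationship is not
meaningful for damage maps). Family-wise error is controlled by the
permutation distribution of the *maximum* t over in-mask voxels: when the
number of distinct group assignments is within the permutation budget
(default 5000) all of them are enumerated and the test is exact; otherwise a
seeded sample of distinct relabelings is drawn, always including the observed
one, which guarantees p ≥ 1/n_permutations and validity. Voxels with zero
pooled variance get t = 0 and can never be significant. Numerically, each
voxel is centered across subjects before the permutation loop (the t
statistic is shift-invariant) and the engine then runs in single precision —
centering removes the large-offset cancellation that would otherwise
dominate single-precision sums, and the permutation null needs no more than
~4 significant digits.

Harmonization utilities follow common practice: mirroring over the
left/right world axis (`flip_x`; requires an x-axis-aligned grid symmetric
about the flip plane, and flipping twice is the identity) and Gaussian
smoothing parameterized by FWHM (σ = FWHM/(2√(2 ln 2)), per-axis σ in voxel
units from the affine). Smoothing uses reflecting boundaries, which conserve
the total map sum exactly; it is intended for patient-derived maps only —
predictions are already smooth, being averages over many subjects.

## Synthetic data: what it emulates and what it does not

A bundle is a resampled centerline copied per streamline with a random
lateral offset (perpendicular to the bundle axis). By default the two ends
of each streamline receive *independent* offsets, linearly interpolated
along the arc ("fanning"). This matters: with rigid parallel copies, the
streamlines selected by a small lesion all lie within the lesion's own
column, so small-lesion maps are trivially consistent across subjects and
reliability *falls* with lesion size — the opposite of what is observed in
patient data. With fanning, the few streamlines a small lesion catches
diverge unpredictably elsewhere, so sparse selections produce noisy maps and
reliability *rises* with lesion volume, which is the behaviour the package
must reproduce. `fan=False` restores rigid copies.

A database applies one rigid random translation per subject (default SD
0.5 mm), emulating residual spatial-normalization error; it is the only
inter-subject deformation modelled, which keeps ground truth analytic.
Synthetic patients are database draws with a larger misalignment (default 3×
the database SD) — normalizing a lesioned brain is substantially less
accurate than a healthy one — and their damage maps use the patient
selection rule (2-mm perilesional endpoint dilation).

The standard validation scene (`two_bundle_scene`) uses a 33³ grid of 2-mm
voxels centred on the origin. The odd grid size is deliberate: it puts voxel
centers on even world coordinates so the bundle axes thread voxel centers.
(On an even-sized grid the axes fall exactly on voxel boundaries, and
sub-voxel translations slosh counts between neighbouring voxels, inflating
the across-subject SD several-fold.) Bundles hold 200 streamlines with 1-mm
lateral SD; a 6-mm spherical lesion sits on bundle A.

These generators do **not** simulate diffusion signal, tracking errors,
crossing-fibre ambiguities, nonlinear warps or realistic anatomy. Passing
the synthetic validation therefore shows that the *pipeline arithmetic* is
correct and internally calibrated — not that real normative predictions
reach any particular reliability on clinical data.

## Simulation studies (`disconnmap.experiments`)

*Deviation-score calibration.* 100 synthetic patients are drawn per study
from a 30-subject prediction's own mean and total deviation, truncated at
zero (counts are nonnegative). Scoring is restricted to voxels whose mean
lies ≥ 3 predicted deviations above zero: there the truncated tail mass is
0.13% and biases the expected score by < 0.3%, while the eligible set (the
~27-voxel bundle core) is stable across database draws. (A stricter ≥ 4
cut-off would be even cleaner statistically but empties entirely for some
draws, since the across-subject SD fluctuates coherently.) Finite voxel
count gives E[score] ≈ 0.99; the replicate mean is expected within
1.00 ± 0.03.

*Null FWE rate.* 200 datasets of two groups of 10 maps, each 4-mm-smoothed
Gaussian white noise on a 20³ grid, tested with 1000 relabelings at
α = 0.05. The fraction of datasets with any significant voxel estimates the
family-wise error, which the max-T construction keeps ≤ α up to binomial
error (≈ ±0.03 at 200 simulations).

*Lesion-size curves.* Three lesion radii (1.5 / 2.5 / 5 mm) × 20 replicates
on sparse fanning bundles (30 streamlines, 4-mm lateral SD, 10 subjects),
with the lesion placed one lateral SD off the bundle axis — the regime where
a misaligned patient can miss the lesion's streamlines entirely. External
reliability per replicate is the Fisher mean over 5 patients; a patient
whose damage map is empty contributes r = 0 (dropping such patients would
overstate external reliability exactly where the prediction fails). Expected
behaviour: internal and external reliability rise monotonically with lesion
volume, with external ≤ internal at the smallest radius.

Problem sizes throughout (grid 20–33³, 25–200 streamlines per bundle,
10–30 subjects, ≤ 1000 relabelings) were chosen so each study completes in
seconds to a couple of minutes while leaving the measured quantities' Monte
Carlo error well inside the tolerances quoted above.

## Known limitations

- Rigid translation understates real inter-subject variability; absolute
  reliability values from the synthetic scenes should not be compared to
  values from patient cohorts.
- No resampling or registration: all inputs must already share a grid
  (affine mismatches raise errors rather than being resolved).
- Connectivity-matrix (parcel-to-parcel) disconnection outputs, covariates
  in the group model, cluster-extent inference and two-sided tests are out
  of scope.
- The exponential lesion-size fit assumes a monotone saturating trend; it is
  a description of the data, not a mechanistic model.
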