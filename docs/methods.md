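# Methods

`mipscsf` implements a complete analysis chain linking cerebrospinal-fluid
(CSF) volume loss to magnetic-induction phase-shift (MIPS) signal change
during intracerebral hematoma expansion, together with synthetic data
generators that stand in for the animal experiments. This note records the
models, the defaults and why they were chosen, the numerical conventions,
and what the synthetic validation does and does not demonstrate.

## Physiological background and model

An expanding intracranial mass is initially buffered by displacement of
CSF (the Monro–Kellie compensation mechanism): intracranial pressure stays
near normal while CSF volume falls, and rises rapidly once the
compensation reserve is exhausted. CSF has by far the highest electrical
conductivity of the main intracranial compartments (several-fold above
gray matter, white matter and blood around 10 MHz), so a non-contact
phase-shift measurement across the head is dominated by the CSF
compartment. The package's working model is therefore:

* **CSF compensation** — CSF volume is piecewise linear in injected blood
  volume `b` with a single breakpoint:

  `csf(b) = V0 + s_pre * min(b, b*) + s_post * max(0, b - b*)`,

  with both slopes nonpositive, `|s_post| <= |s_pre|`, clipped at zero.
  A single breakpoint is the simplest shape with one inflection, which is
  all the mean cohort trajectory identifies.
* **Phase response** — the dense phase signal is linear in compartment
  volumes:

  `phase(t) = phi0 + a_csf * (csf(t) - csf(0)) + a_blood * max(0, b(t) - b_on)
             + respiration + cardiac + noise`,

  with `a_csf > 0` (CSF loss lowers the phase) and `a_blood >= 0` raising
  it after the onset volume `b_on`, tied by default to the compensation
  breakpoint. The post-reversal rise is a hypothesis about mechanism, not
  a measured response; the hinge form `max(0, b - b_on)` keeps the
  trajectory continuous, which a step-switched blood term would not.
  Respiration (0.7 Hz) and cardiac (4 Hz) cycles enter as additive
  sinusoids; block averaging over 300 samples (6 min) removes them along
  with white noise.

## Default parameters

The injection protocol is 3 ml of autologous blood at constant rate over
54 min (rate 3/54 ≈ 0.0556 ml/min), sampled every 6 min; the blood axis is
the two-decimal grid 0.33 … 3.00 ml used by the packaged cohort tables.
Phase recordings run at 50 samples/min, i.e. 2700 samples per protocol.

Compensation defaults are a least-squares fit of the piecewise-linear
model to the packaged cohort's mean CSF trajectory (breakpoint by grid
search): baseline 0.87 ml, `s_pre = -0.19`, `s_post = -0.06` ml CSF per ml
blood, breakpoint 2.0 ml. Phase-response defaults follow from the mean
phase trajectory the same way: `a_csf = 6.0` °/ml, `a_blood = 1.0` °/ml,
baseline phase 100°. Noise levels are fixed a priori at realistic
magnitudes: 0.1° white phase noise per sample, 0.02 ml volumetry noise per
CSF observation, respiration/cardiac amplitudes 0.2°/0.05°. Cohort
generation draws per-animal parameters uniformly from ranges bracketing
these defaults (baselines 0.65–1.10 ml, breakpoints 1.2–2.4 ml, `a_csf`
4.5–7.5 vs `a_blood` 0.8–1.3 °/ml), reproducing the cross-animal spread of
the packaged tables while keeping the CSF response dominant.

In the packaged cohort data the phase reversal (1.66 ml) sits slightly
before the fitted CSF breakpoint (≈2.0 ml); the generator ties the two
together rather than modelling that lead, since the lead's magnitude is
not identified by nine-point series.

## Conditioning and reversal detection

Raw recordings are reduced by non-overlapping block means (default 300
samples = 6 min per block; a trailing partial block is dropped with a
warning) and normalized to percent of a pre-injection baseline — the mean
of the segment recorded before the infusion starts. Normalization to a
pre-injection reference rather than to the first block is what lets
first-block values straddle 100.

The reversal analysis computes forward finite differences with respect to
injected blood (indexed to the left block), the derivative maximum
(earliest index on ties), and the *reversal section* — all indices
strictly after that maximum, the segment on which the signal sits outside
the overall falling trend. The *reversal point* is the blood value at the
series minimum (earliest index on plateaus). A least-squares polynomial
fit in blood volume (default degree 4, configurable 3–6; degree 4 is the
lowest degree able to represent one interior minimum plus a curvature
change without interpolating nine points) supplies the analytic derivative
curve and its falling-to-rising zero crossing as a continuous feature.
The series argmin is preferred over the fitted-curve argmin for the point
estimate because polynomial minima are systematically biased on asymmetric
V-shaped trajectories (on noise-free synthetic cohorts the degree-4 fit
minimum can land two grid steps from the planted breakpoint; the argmin
never leaves one step). Monotone series report no reversal rather than an
endpoint artifact.

## CSF segmentation and volumetry

Volumes are rescaled to [0, 1] and brain-masked (Otsu threshold, largest
connected component; no bias-field correction or registration). The
segmenter minimizes a fuzzy c-means objective with a spatial
regularization term:

`J(U, V) = Σ_i Σ_k u_ik^m (x_i - v_k)^2
          + β σ̄² Σ_i Σ_k u_ik^m · mean_{j∈N(i)} (1 - u_jk)`

The penalty charges membership in class `k` at voxel `i` by how little
its neighbors belong to `k` — a Markov-random-field-style prior on
membership agreement. Averaging over the neighborhood and scaling by
`σ̄²` (the membership-weighted mean within-class squared deviation,
refreshed each sweep) makes `β` dimensionless: `β = 1` prices full
neighborhood disagreement like one typical within-class deviation. An
unscaled neighbor-sum penalty would exceed the data term by two to three
orders of magnitude on [0, 1] intensities and collapse all memberships to
uniform. Minimization alternates the closed-form membership update (with
the penalty refreshed from the previous sweep, ICM-style) and the usual
centroid update; at `β = 0` this is exactly plain fuzzy c-means, and the
objective is then guaranteed nonincreasing (asserted in tests against an
independently coded textbook implementation).

Defaults: K = 4 classes (white matter, gray matter, blood, CSF —
background removed by the mask), fuzzifier m = 2, β = 0.5, 6-connected
neighborhood, centroid tolerance 1e-4, at most 100 sweeps. Centroids are
initialized from multi-Otsu class means — deterministic, and robust to
strongly unbalanced class sizes, where a random initialization can merge
the small hyperintense CSF class with blood (seeded k-means++ remains as
a fallback for degenerate histograms). Centroids are kept sorted
ascending so the brightest class is always the CSF candidate; argmax ties
break toward the brighter class. The candidate is intersected with a
prepared binary CSF template (an opaque input, as in template-masked
atlas workflows), and volume is voxel count × voxel volume. Segmentation
is fully 3D; masks are unsigned 8-bit NIfTI.

## Phantoms

MR phantoms preserve the study's scanner geometry — 0.5 mm slices and a
160 mm field of view on 320×275 in-plane matrices, i.e. 0.5 × 0.5 × 0.582
mm voxels (0.1455 mm³) — on a desk-scale 96×96×64 grid, so all volumetry
arithmetic is identical to full acquisition size. The brain is an
ellipsoid with a gray-matter shell; the CSF compartment is two mirrored
ellipsoidal ventricles grown voxel-by-voxel from their centers to exactly
`round(volume / voxel_volume)` voxels, so ground truth matches the request
to within half a voxel and realized regions are nested across volumes
(which makes the cohort template simply the largest region, dilated
metrically via a Euclidean distance transform). The hematoma grows the
same way around an injection site in the parenchyma. T2-like contrast
puts CSF strictly brightest (class means 0.35/0.55/0.70/0.92 for
WM/GM/blood/CSF); partial volume is emulated by Gaussian smoothing
(0.6 mm FWHM) and noise is additive Gaussian (a magnitude-image
approximation valid at moderate SNR), sd 0.03.

The packaged validation suite is eight phantoms tracing a
compensation-like trajectory (CSF 1.05 → 0.34 ml against blood
0.33 → 2.66 ml). Median absolute volumetry error at default configuration
is required to stay within 10%; errors grow toward the small-volume end
of the trajectory because partial-volume smoothing affects a larger
fraction of a smaller compartment's voxels.

## Statistics

The two modalities are synchronized on injected blood volume (the
constant-rate infusion makes blood a shared clock between asynchronous
instruments). The regression sample is the nine per-time-point
cross-animal means — the convention forced by the ANOVA degrees of
freedom (2, 6, 8) of the analysis this package reproduces. The battery
comprises ordinary least squares of mean phase on (mean CSF, blood) with
the classical model summary (R, R², adjusted R², standard error of the
estimate, F with its upper-tail p); first-order partial correlations by
the closed-form recursion with two-sided t tests on n−3 degrees of
freedom (verified against a residual-regression oracle to 1e-10); and the
Pearson correlation of the fitted derivative curves of the two mean
trajectories (finite-difference variant reported alongside). Exact
classical distributions are used rather than permutation, two-sided
throughout, with no multiple-testing correction — matching the analysis
style being reproduced. No per-animal mixed-effects modelling is
attempted, and the report makes no causal claims.

## What the synthetic validation shows — and does not

Passing tests demonstrate that the pipeline's arithmetic is exact (block
means, voxel volumetry, ANOVA identities), that its estimators agree with
independent oracles, that it recovers planted structure (reversal
location within one blood step; CSF-dominance of the partial
correlations in ≥90% of replicates; volumetry within 10% median error)
under the generator's assumptions. The generators emulate trajectory
shapes, periodic contamination, cross-animal spread, tissue contrast and
partial volume — not coil physics, real anatomy (sulcal/cisternal CSF
geometry, bias fields, motion), or any mechanism by which blood raises
the phase after compensation failure. Accuracy on real recordings and
acquisitions is therefore not established by these tests, and the
published single-animal volumetry figures (1.18 ml manual vs 1.10 ml
algorithmic) are not reproducible without the original acquisitions,
which are not deposited.

## Numerical conventions

Polynomial fits run in a scaled window and are converted back to the data
domain. Argmax/argmin ties take the earliest index, except the CSF class
argmax which prefers the brighter class. Finite differences are forward
differences indexed to the left block. Voxel coordinates are 0-based
array indices; world coordinates follow the NIfTI affine with spacing on
the diagonal. All randomness flows from explicit integer seeds through
`numpy.random.Generator`; equal seeds reproduce byte-identical outputs.
File writes are atomic (temp file + rename). Degenerate inputs —
constant volumes, collinear predictors, marginal correlations of ±1,
monotone series, over-capacity volume requests — raise typed errors
rather than returning artifacts.

## Problem sizes used by the validation scripts

The packaged analyses run on the 8-animal × 9-time-point tables; synthetic
validation uses 50 reversal replicates (25 noise-free + 25 noisy cohorts
of two animals), 50 eight-animal cohorts for the partial-correlation
ordering, and the eight-phantom suite at the default 96×96×64 grid.
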