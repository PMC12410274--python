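# Methods

## The model

Spatial attention is modeled as a Gaussian gain field (the *attention
field*, AF) centered on the attended location, with standard deviation
σ₁ encoding attentional precision: a task confined to a 0.1°-radius
circle at fixation recruits a narrow field, a task spread over the whole
display a wide one.  A voxel's stimulus-driven population receptive
field (SD-pRF) is a second Gaussian with center μ₂ and size σ₂.  Their
interaction is pointwise multiplication; the measurable attention-driven
pRF is the Gaussian description of the product.

With no offset the product of two Gaussians is itself Gaussian:

    μ₃ = (μ₁σ₂² + μ₂σ₁²) / (σ₂² + σ₁²)
    σ₃² = σ₁²σ₂² / (σ₁² + σ₂²)

μ₃ is a convex combination of the attended position and the pRF center,
so (i) narrower attention attracts pRFs more, and (ii) at fixed
attentional precision, larger pRFs are attracted more — the two
monotonicities the package's acceptance suite verifies on a parameter
lattice.  This plain model, however, predicts attraction that grows
without bound with distance from the attended locus, and product
amplitudes that vanish there.

The offset variant (*AF+*) multiplies the pRF by `a·A(x) + b` instead.
The constant b bounds attentional influence: far from the attended
locus the field term vanishes relative to b and the attention-driven
pRF approaches the SD-pRF.  The product is a two-Gaussian mixture, so
the attention-driven pRF is estimated by nonlinear least squares — a
single Gaussian fit to the profile evaluated on a dense grid,
initialized at the profile's center of mass.  Because the profile is
bounded above by a multiple of the SD-pRF, the evaluation grid spans
both centers ±8σ₂ with spacing min(σ₁, σ₂)/25 (capped per batch);
at gain 1/offset 0 the refit agrees with the closed form to 1e-3.

Only centers (and sizes) of the resulting Gaussians are used downstream;
amplitudes are carried but discarded by the difference analyses, since
the plain model's amplitudes vanish for distant pRFs and the offset
model's are not separately informative here.

One property of the shared-offset AF+ model worth flagging: in
small-pRF areas the *distributed* field still attracts slightly at 4–5°
eccentricity where the focused field no longer reaches, so the
distributed-minus-focused difference dips a few hundredths of a degree
below zero in the far periphery before decaying.  This is intrinsic to
the model, matches the "peripherally there are no differences" regime,
and is why the sign-structure checks assert positivity within 2° rather
than everywhere.

## Radial reduction

Both experimental attention fields are isotropic and centered at
fixation, so the 2-D interaction reduces to the 1-D radial axis through
the pRF center: eccentricity maps to the 1-D center, size is unchanged,
polar angle is preserved.  Anisotropic fields or off-fixation loci are
out of scope.

## Stimulus and forward model

One run is a block design: 14 TRs passive fixation, 224 TRs attention
task, 21 TRs fixation (TR = 1.5 s).  The visual-field mapper starts 10
TRs after task onset: eight passes of a 1.25°-wide bar advancing 0.625°
per TR across a 10°-diameter circular aperture, in four orientations ×
two directions, with a 10-TR task-only gap after every second pass and
the remaining task TRs padded at the end.  The published stimulus
durations do not tile the 224-TR task block exactly (and the two
fixation-block descriptions disagree between seconds and TRs); the
TR-denominated block lengths are treated as authoritative and the
end-of-task pad absorbs the remainder.  The bar is reduced to its
binary aperture on a pixel grid in degrees (default 11.2° × 5.6° at 10
px/deg — the display is shorter than the aperture, so vertically-moving
bars are clipped near the aperture edge exactly as on the real screen).

The BOLD forward model is linear: per-TR overlap of the unit-peak pRF
Gaussian with the aperture (pixel sums scaled by pixel area, so overlap
approximates the integral in deg² and is resolution-independent),
convolved with a canonical double-gamma HRF (response gamma peaking at
6 s, undershoot at 16 s, ratio 1/6, sum-normalized; the source names no
parameterization, so these conventional values are configurable), then
scaled and shifted by amplitude and baseline.  Task blocks enter as an
HRF-convolved boxcar plus onset/offset impulses.

## Synthetic data

The generator emulates the study's measured quantities with known
ground truth:

- Six visual areas (V1, V2, V3, hV4, LO, IPS) with linear
  size–eccentricity relations whose slopes/intercepts grow up the
  hierarchy (V1: 0.25° + 0.12/°, up to IPS: 1.0° + 0.75/°) — typical of
  published retinotopy.
- Eccentricities sampled area-uniformly on [0.05, 5]°, polar angles
  uniform, sizes from the area relation with 20% lognormal scatter.
  Amplitudes normalized so each voxel's peak response is ~3 percent
  signal; with an aperture-limited bar this yields realistically weaker
  modulation for large peripheral pRFs.
- Attention applied by the AF+ interaction with defaults
  σ₁ = 0.5° (focused), 5.0° (distributed), gain 1, offset 0.1 — the
  regime in which small-pRF areas show foveally-confined attraction
  differences and large-pRF areas plateau.
- Task-response betas per condition follow smooth exponential profiles
  whose distributed-minus-focused difference crosses zero at the 0.3°
  task boundary (the magnitudes are order-of-magnitude choices; the
  sign structure is the modeled feature).
- White Gaussian noise in percent-signal units (an AR(1) extension
  would be straightforward but is not modeled); participants are
  independent population draws, optionally with lognormal between-
  subject jitter on the AF widths.
- Behavior is an equal-variance signal-detection observer: targets at
  rate 1/12, hit probability Φ(d′/2 − c), false alarms Φ(−d′/2 − c),
  defaults d′ = 2.7 and c = 0, matching the study's operating point.

What passing recovery tests do **not** show about real data: the
generator's noise is white, its pRFs are exactly Gaussian and
stationary, the HRF is known and shared, and the independent mapper
differs from the task runs only in the absence of attention effects.
Violations of any of these in real measurements would add biases the
synthetic pipeline cannot expose.

## Fitting pipeline

pRF inversion runs on the truncated task segment (default 4 TRs trimmed
at each end of the task block; the source says only "transient
responses" with no count): an exhaustive grid over x, y ∈ [−5.5, 5.5]°
(0.25° steps) × 20 log-spaced sizes in [0.1, 6]°, with amplitude ≥ 0
and baseline solved linearly per node, then bounded nonlinear
refinement (±1 grid step in position, size in [0.05, 10]°) from the
best node.  Refinement is kept only if it does not lower R².  Estimates
are filtered on R² ≥ 0.1 (inclusive) and eccentricity < 5° (strict),
and — in the multi-condition pipeline — a voxel must survive the filter
in every condition.

The task GLM runs on the full series with OLS over [intercept, pRF
prediction, task boxcar, onset impulse, offset impulse], the last three
HRF-convolved; the boxcar beta is the task response.  Rank deficiency
raises an error naming the collinear columns.

Condition differences (distributed minus focused, of eccentricity or
task betas) are binned by *independent-condition* eccentricity —
half-open bins, a foveal [0, 0.3)° bin plus eight log-spaced bins to
5° — never by either attention condition's own estimates, to avoid
circularity and regression to the mean.  Bin "centers" are the mean
member eccentricities (midpoints for empty bins) so curve fits are
anchored where the data sit, and each bin also records the mean
independent pRF size of its members.  Participant-bin cells with fewer
than three member voxels are treated as missing in the recovery
pipeline: a mean difference of noisy estimates from one or two voxels
is uninformative and, left in, dominates downstream fits.

## AF fitting to difference curves

A single focused/distributed field pair — and, for AF+, a single shared
gain and offset — is fit across all areas by weighted least squares on
the binned difference curves.  Per-bin weights are the inverse standard
errors of the across-participant means (clipped below at 0.2× their
median; unit weights when no standard error is estimable), so bins are
weighted by the precision they actually carry.  Where a series provides
measured mean pRF sizes per bin, those are used as σ₂ in place of the
size–eccentricity relation: with multiplicative size scatter the
relation's value at the bin center misstates the members' mean size and
biases the recovered focused width by ~18%; the measured means reduce
that to the residual Jensen effect (~9% at 20% scatter, <1% at zero
scatter).  The optimizer restarts from five log-spaced focused-width
initializations (bounds σ₁ ∈ [0.05, 50]°, a, b ∈ [0, 100]); in the AF+
variant only the ratio a/b is identified, since rescaling both leaves
the refit Gaussian's center and size unchanged.  Non-convergence is
flagged on the result, not raised.

## Statistics

- d′ = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate), with the log-linear
  correction (+0.5 to each cell, +1 to each denominator) only when a
  rate is exactly 0 or 1.
- The permutation null shuffles target labels across trials with the
  response stream fixed (the scheme is not specified by the source;
  label shuffling is the natural exchangeable null here), with the
  add-one exceedance p.
- Exponential fits use y(e) = amp·e^(−e/decay) + asymptote — three
  parameters accommodate both decaying and saturating shapes — fit to
  across-participant bin means; uncertainty comes from resampling
  participants with replacement (default 1000 resamples, refit from the
  point estimate, pointwise 2.5/97.5 percentiles).
- Wilcoxon signed-rank tests are two-sided, exact for n ≤ 25 (normal
  approximation with continuity correction otherwise, or when zeros/
  ties preclude the exact null), with Benjamini–Hochberg FDR across the
  areas tested per contrast.  All-zero difference vectors are flagged
  as undefined and excluded from the family.

## Problem sizes and numerical choices

The end-to-end recovery experiment uses 5 synthetic participants × 500
voxels × 3 conditions (focused, distributed, independent), at 8 px/deg
(the minimum resolution that resolves the bar), with shared grid-stage
predictions across voxels and conditions.  Batched damped least-squares
(Levenberg–Marquardt) row-fitters handle the thousands of Gaussian
refits in the AF+ interaction and the exponential bootstrap; both
early-terminate on negligible steps and are cross-checked against scipy
fits in the test suite.  Degenerate inputs are handled explicitly:
all-zero interaction profiles raise, constant BOLD series return R² = 0
rather than raising, and empty bins propagate as missing values.

## Known limitations

- The radial 1-D reduction assumes isotropic, fixation-centered fields.
- A single shared offset across areas is the default; the per-area
  falloff pattern suggests the offset may genuinely vary by area, and a
  per-area offset is a natural extension of the fitting interface.
- Recovery of the AF+ gain/offset pair is only up to their ratio.
- The white-noise model understates the temporal autocorrelation of
  real BOLD; recovery tolerances under realistic noise spectra would be
  wider.
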