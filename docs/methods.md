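# Methods

## Signal model

The package models the diffusion-weighted magnitude signal of perfused
tissue as a biexponential:

S(b) = S0 · e^(−bD) · [F · e^(−bD*) + (1 − F)]

with `F` the microvascular volume fraction (stored internally as a fraction
in [0, 1], converted to percent only at reporting boundaries, which keeps
the optimizer in one unit system), `D*` the pseudo-diffusion coefficient and
`D` the tissue diffusion coefficient, both in mm²/s. `F·D*` is always
derived as the exact product, never fitted independently. The model is
defined for arbitrary b ≥ 0 so that simulation can use denser grids than the
acquisition scheme.

The default acquisition scheme is 14 b-values from 0 to 650 s/mm² in steps
of 50, with a high-b cut-off of 400 s/mm² separating the diffusion-only
regime (five b-values, 450–650, lie above it). At typical cord parameters
the perfusion term contributes < 10⁻⁵ of the signal above the cut-off, which
is what licenses the segmented estimate of `D` from the tail.

## Fitting algorithms

Hard physical bounds constrain every fit: F ∈ [0, 0.20] (fraction),
D* ∈ [0.3, 50]×10⁻³ mm²/s, D ∈ [1.5, 54]×10⁻⁴ mm²/s. S0 is fitted as a
free nuisance parameter bounded to [0.5, 1.5]× the observed b=0 signal —
fitting it absorbs noise in the b=0 frames; a normalisation-only mode
(`fit_s0=False`) fixes it instead.

**One-step.** (1) A prior `D` is estimated from the high-b tail by
log-linear least squares (the closed-form optimum of the mono-exponential
fit on exact data; a nonlinear refinement adds nothing on noiseless input
and a dependence on an optimizer where none is needed). The prior seeds one
individual of the initial population and can optionally narrow the `D`
search interval to [0.5, 2.0]× the prior (`narrow_D_from_prior`); by default
the published global bounds alone constrain `D`, and they are always
enforced as the outer constraint either way. (2) All four parameters are
fitted over all b-values by Differential Evolution (best/1/bin, population
15× the number of free parameters, mutation dithered in [0.5, 1.0],
recombination 0.7, relative convergence tolerance 1e-7, at most 1000
generations, explicit seed; population updates deferred and the objective
vectorized so one generation is a single array evaluation). (3) A
fine-tuning pass shrinks each parameter's window to [0.95, 1.05]× its
stage-2 estimate, intersected with the global bounds so refinement can never
exit physical ranges; if an estimate sits on a bound the window becomes
one-sided, and a window that collapses to a point freezes that parameter.
The refinement is a bounded trust-region least-squares polish — inside a
±5 % box the problem is locally smooth, so a global optimizer would be
wasted there.

**Two-step (segmented).** `D` is fixed to the stage-1 mono-exponential
estimate (clipped into the `D` bounds) for the whole fit; Differential
Evolution then runs over (S0, F, D*) only, followed by the same fine-tuning
of F and D* with `D` still fixed. The returned `D` therefore equals the
closed-form high-b slope bit-for-bit, which the tests assert without
invoking the optimizer.

Degeneracies: if the global-stage `F` is ≤ 1e-6 there is no perfusion
compartment and `D*` is unidentifiable; it is reported at its lower bound
and flagged (`provenance["Dstar_unidentifiable"]`) rather than left at an
arbitrary optimizer value. An all-zero decay is rejected; optimizer
non-convergence returns the best-found parameters with `converged=False`
instead of raising.

**Voxel-wise vs ROI-wise.** Voxel-wise fitting runs the configured
algorithm independently in every masked voxel of the repetition-averaged
volume, one diffusion-encoding direction at a time, producing NaN-padded
parameter and R² maps. Results are a pure function of the decay for a fixed
configuration, so byte-identical decays are fitted once and shared; fits are
independent of voxel order. ROI-wise fitting first forms, per slice, the
probability-weighted average decay Σ(pᵢ·sᵢ)/Σ(pᵢ) over the probabilistic
ROI, then fits that single decay; slices without ROI support are absent from
the result, never zero-filled. Repetition averaging happens before the
weighted ROI average; with fixed weights the two averaging orders commute,
so nothing hinges on the choice.

## Synthetic phantom

The generator emulates a two-session scan-rescan cohort in a common space
(registration, motion, distortion and cardiac-gating fluctuations are out of
scope and not simulated):

* **Geometry** — an elliptical cord cross-section (in-plane radii ≈ 4.5 and
  3.5 voxels on the default 16×16×4 grid, ≈ 180 cord voxels), a central
  grey-matter ellipse with a linear soft boundary band, and a white-matter
  annulus tapering at the cord edge; WM + GM probabilities never exceed 1.
  Slices map onto three vertebral-level analogues. Geometry is identical
  across subjects and sessions.
* **Parameter hierarchy** — subject-level tissue parameters are drawn from
  Normal(tissue mean, between-subject SD) and clipped into the fit bounds;
  each session adds an independent zero-mean Normal perturbation; `D` is
  additionally scaled per direction by (1.0, 0.9, 1.1) to mimic the
  direction-dependent diffusivity that motivates per-direction fitting (the
  factors are a modelling choice). Tissue means default to the cohort
  voxel-wise one-step session-1 values (WM: F 5.45 %, D* 24.41×10⁻³,
  D 3.74×10⁻⁴; GM: F 9.61 %, D* 17.14×10⁻³, D 4.17×10⁻⁴ mm²/s) with the
  corresponding between-subject SDs.
* **Session effect** — no within-subject variance decomposition is published
  for these parameters, so the session SDs are a calibration: 5 % of the
  tissue mean for F, 3 % for D*, 2 % for D, chosen so simulated voxel-wise
  wsCVs land in the few-percent range reported for cord scan-rescan data
  (expected wsCV ≈ 79.8 · σ_session/μ under the paired-scan formula).
* **Noise** — complex Gaussian noise of SD S0/SNR added to the noiseless
  signal before taking the magnitude, i.e. Rician, the distribution of
  magnitude MRI; at high b and low SNR the positive Rician bias is
  measurable and is tested against the analytic Rician mean. The default
  single-repetition b=0 SNR of 27 yields ≈ 27·√20 ≈ 120.7 on the
  20-repetition average, matching the SNR regime the fitting algorithms were
  designed for. `snr_single_rep=inf` gives the exact noiseless limit
  (a Gaussian-noise switch is not provided; tests that need Gaussian draws
  construct them directly).
* Generation is bit-reproducible under a fixed seed; ground truth (subject,
  session and per-voxel values) is stored losslessly alongside the data.

What passing tests on this phantom do **not** show: robustness to motion,
susceptibility distortion, imperfect registration, partial-volume mixtures
beyond the soft boundary band, cardiac-driven signal fluctuations, or
spatially correlated noise. Real-data wsCVs will generally exceed the
phantom's.

## Reliability statistics

* **wsCV** = 100·SD(x₁, x₂)/mean(x₁, x₂) per subject, with the sample (n−1)
  SD — hence 100·|x₁−x₂|/(√2·mean) — the standard convention for paired
  scans (the denominator choice is not dictated by the formula's usual
  statement, so it is fixed and documented here).
* **ICC(A,1)**: two-way model, absolute agreement, single measures,
  (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)) from the two-way mean
  squares; computed closed-form and cross-checked in the tests against an
  independent OLS-ANOVA route and against pingouin. Qualitative labels
  follow the poor < 0.4 < fair < 0.6 < good < 0.75 < excellent scale. A
  fully constant table raises a degenerate-variance error; identical
  sessions with real between-subject spread give a legitimate ICC of 1.
  Note the per-table estimator is biased downward in small samples (about
  −0.05 at n=10 for a true value of 0.5); consistent recovery across many
  replicates requires pooling the mean squares before forming the ratio,
  which is what the recovery test does.
* **Bland–Altman**: differences oriented session1 − session2 (a convention,
  stated on every output); bias ± 1.96·SD(differences) as the 95 % limits of
  agreement, with the paired (mean, difference) points returned for
  plotting.
* **Pearson r** between the session columns (scipy).
* **2×2 repeated-measures ANOVA** on the wsCVs with approach
  (voxel-wise/ROI-wise) and algorithm (one-step/two-step) as within-subject
  factors: balanced closed-form decomposition with subject as blocking
  factor, each effect tested against its effect-by-subject interaction mean
  square; run separately per ROI and parameter (α = 0.05). A plain two-way
  fixed-effects variant is available behind `repeated_measures=False` for
  comparison. Null calibration over 2000 exchangeable-noise replicates gives
  empirical type-I error within [0.040, 0.060] for all three effects.
* No multiple-testing correction is applied across ROIs/parameters; raw
  p-values only, stated in the report.

## Pipeline conventions

Voxel indices are 0-based, slices run along the third axis, and all masks
and maps share one grid — there is no resampling inside the pipeline.
SNR QC maps are mean/SD across the b=0 repetitions × √Nrep inside the
eroded cord mask; zero-SD voxels (which occur in noiseless simulation) are
excluded from the summary with a count rather than treated as errors.
Mask erosion uses a discrete spherical structuring element (radius 1 ≈ the
6-connected cross) applied before metric extraction to limit CSF partial
volume. Parameter maps are averaged across the three directions voxel-wise
(missing voxels propagate); voxel-wise ROI summaries use probability-
weighted means for consistency with the ROI-wise weighting (plain
thresholded means via `weighted_extraction=False`); ROI-wise summaries are
unweighted means of the per-slice fits over the configured level range
(level slice counts are equal by construction; with unequal counts the mean
is per-slice, not per-level). Every run writes a manifest naming seeds,
bounds, cut-off, erosion radius and configurations so QC differences
between runs are diffable.

## Problem sizes

Default test and validation runs use a 16×16×4 (≈ 180 cord voxels) or
12×12×4 phantom with 2–5 subjects, chosen as the smallest geometries that
still exercise soft tissue boundaries, erosion shells and three vertebral
levels; statistical calibrations use 1000–2000 replicates, which put
Monte-Carlo error well below the asserted tolerances. Noiseless end-to-end
runs exploit the decay memoization noted above, making the full four-
configuration pipeline cheap; noisy validation runs use one direction and
session at a reduced grid.

## Known limitations

* `D*` is weakly identified when `F` is small; at the cord's F ≈ 5 % and
  realistic SNR, voxel-wise `D*` estimates hit the bounds regularly. The
  flagging described above makes this visible but does not fix it.
* The two-step `D` inherits any residual perfusion contamination of the
  high-b tail; at default parameters this is negligible (< 10⁻⁵ relative)
  but grows for very low `D*`.
* The phantom's geometry is convex and identical across slices; atrophy,
  lesions and level-dependent cord shape are not represented.
* Bayesian and neural-network fitting approaches are deliberately out of
  scope, as is any estimation along the inferior–superior axis.
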