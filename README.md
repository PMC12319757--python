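# cordivim

Constrained intravoxel incoherent motion (IVIM) model fitting and test–retest
reliability analysis for spinal-cord diffusion-weighted MRI, with a synthetic
cervical-cord phantom for validation.

## The problem

Diffusion-weighted MRI of perfused tissue mixes two signal sources: water
diffusing in tissue and blood water moving pseudo-randomly through the
capillary network. The IVIM model separates them with a biexponential decay

```
S(b) = S0 · exp(−b·D) · [ F · exp(−b·D*) + (1 − F) ]
```

where `F` is the microvascular volume fraction, `D*` the pseudo-diffusion
coefficient (proportional to capillary blood velocity), `D` the tissue
diffusion coefficient, and the derived product `F·D*` relates to blood flow.
In the cervical spinal cord these parameters are candidate perfusion
biomarkers, but before they can be used longitudinally one must know how
repeatable they are across scan sessions — and how much that repeatability
depends on the fitting strategy.

`cordivim` provides:

* **Constrained fitting** of the IVIM model, with two standard algorithms:
  - *one-step*: a prior mono-exponential estimate of `D` from b > 400 s/mm²,
    then a global Differential Evolution fit of (S0, F, D*, D) over all
    b-values inside hard physical bounds (F ∈ [0, 20] %,
    D* ∈ [0.3, 50]×10⁻³ mm²/s, D ∈ [1.5, 54]×10⁻⁴ mm²/s), then a fine-tuning
    pass confined to 95–105 % of each estimate;
  - *two-step (segmented)*: `D` fixed to the high-b mono-exponential slope,
    then (S0, F, D*) fitted and fine-tuned with `D` held fixed.

  Both run *voxel-wise* (fit each voxel, then average parameters over an ROI)
  or *ROI-wise* (fit the probability-weighted average decay per slice).
  The fitter is scikit-learn shaped (`IVIMFitter(...).fit(X)` with fitted
  attributes `params_`, `r2_`, `converged_`).

* **Test–retest statistics**: within-subject coefficient of variation
  (wsCV = 100·σ/μ across the two sessions), ICC (two-way model, absolute
  agreement, single measures), Bland–Altman bias and 95 % limits of
  agreement, Pearson correlation, and a 2×2 repeated-measures ANOVA on the
  CVs with fitting approach and algorithm as within-subject factors.

* **A synthetic phantom**: multi-subject, two-session, three-direction
  cervical-cord-like datasets with elliptical cord geometry, a central
  grey-matter region with elevated `F`, between-subject and between-session
  variance components, and Rician magnitude noise at a configurable
  single-repetition SNR (default 27, i.e. ≈ 120 after averaging 20
  repetitions). Ground truth is stored losslessly for recovery scoring.

* **A pipeline and CLI** (`cordivim simulate | fit | reliability |
  run-study`) covering repetition averaging, voxel-wise SNR QC maps
  (mean/SD of the b=0 repetitions × √Nrep), spherical mask erosion at the
  cord periphery, per-direction fitting with direction averaging of maps,
  metric extraction over vertebral levels, and tidy CSV/NIfTI/JSON outputs.

## Worked example

Recover the white-matter cohort mean parameters from a noiseless decay on
the 14-b-value scheme (0–650 s/mm², step 50):

```python
from cordivim import BValueScheme, IVIMParams, FitConfig, forward_signal, fit_one_step

scheme = BValueScheme()                       # b = 0, 50, ..., 650 s/mm^2
truth = IVIMParams(S0=1.0, F=0.0545, Dstar=24.41e-3, D=3.74e-4)
decay = forward_signal(truth, scheme)         # noiseless white-matter decay
res = fit_one_step(decay, FitConfig(seed=0))
print(f"F  = {res.params.F_percent:.2f} %")
print(f"D* = {res.params.Dstar * 1e3:.2f} x 1e-3 mm^2/s")
print(f"D  = {res.params.D * 1e4:.2f} x 1e-4 mm^2/s")
print(f"F.D* = {res.params.FDstar * 1e4:.2f} x 1e-4 mm^2/s")
print(f"R^2 = {res.r2:.6f}")
```

prints

```
F  = 5.45 %
D* = 24.41 x 1e-3 mm^2/s
D  = 3.74 x 1e-4 mm^2/s
F.D* = 13.30 x 1e-4 mm^2/s
R^2 = 1.000000
```

i.e. the constrained one-step fit returns the generating microvascular
fraction, pseudo-diffusion and diffusion coefficients exactly (R² = 1 on
noiseless data). A complete simulated study — phantom generation, all four
fitting configurations, reliability battery — runs with:

```bash
cordivim run-study --out scratch/study --seed 1 --n-subjects 5
```

which writes `test_retest.csv` (one row per subject × ROI × parameter ×
configuration with both session values), `reliability_report.csv` (wsCV
mean ± SD, ICC with its qualitative label, Bland–Altman bias and limits,
Pearson r), per-ROI ANOVA tables and a provenance manifest.

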