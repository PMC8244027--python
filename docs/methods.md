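# Methods

`rsfavasc` implements a residual-based test of whether age-related changes
in resting-state BOLD signal variability (RSFA) are attributable to
cardiovascular and cerebrovascular physiology rather than to neural
activity per se.  This note documents the statistical model, the numerical
choices, and what the synthetic validation cohort does and does not
emulate.

## The two-stage residual model

For each RSFA target `y` (a voxel's values across subjects, or a subject's
loading on an ICA component), stage one fits

    y = β₀ + β₁·CBF + β₂·CVH + γ·Covs + ε

by robust multiple linear regression, where the predictor set varies across
six nested models:

| model | predictors           | question answered |
|-------|----------------------|-------------------|
| I     | covariates only      | baseline age effect on RSFA |
| II    | + CBF                | does cerebral blood flow explain it? |
| III   | + CVH                | does cardiovascular health explain it? |
| IV    | + CBF + CVH          | do both jointly explain it? |
| V     | + GMV                | does grey-matter atrophy explain it? |
| VI    | + GMV ⊥ CVH          | does atrophy *independent of CVH* explain it? |

Covariates of no interest are sex (±0.5), head motion and handedness
(z-scored), plus the CSF signal whenever GMV is a predictor (to absorb
non-morphological confounds in T1-derived volumes).  Age **never** enters
stage one.  Stage two computes the Pearson correlation of the stage-one
residuals with age (two-sided p from the t transform with n−2 df) and
applies Benjamini–Hochberg FDR at q = 0.05 across targets.  A residual–age
correlation that survives conditioning means the predictors could not
account for the age-related variability; the central hypothesis predicts
that Model IV abolishes all discoveries.

At the voxel level, CBF and GMV enter voxel-matched: the RSFA values of
voxel v are predicted by the CBF/GMV values of the same voxel.  At the
component level, the full CBF/GMV loading matrices enter as shared columns.

**Robust fitting.** "Robust regression" is realised as iteratively
reweighted least squares with the Tukey bisquare ψ, tuning constant 4.685,
scale re-estimated each iteration as median(|r|)/0.6745, at most 50
iterations, convergence at 1e-8 relative coefficient change.  This matches
the default of the common robust `fitlm`-style routines (verified against
`statsmodels.RLM` to ~1e-6 in the tests).  The kernel is batched over
voxels (per-voxel designs in a single einsum-based solve), which is what
makes 4096 voxel-wise robust fits per model take seconds.  Stage-two
p-values use ordinary Pearson correlation; Spearman is not needed because
residuals are already robustified.

## RSFA estimation

RSFA is the standard deviation over time of the nuisance-GLM residual of a
BOLD series.  The design holds: intercept, linear trend, the six
realignment parameters with backward first differences (zero first element)
and squares, mean WM and CSF signals (voxels with tissue probability
> 0.7) with the same expansions, and a DCT set at every frequency *outside*
the 0.0078–0.1 Hz band (DCT order k maps to frequency k/(2·N·TR)).
Filtering and nuisance removal therefore happen in one simultaneous fit,
never sequentially.  Columns that do not increase the design rank are
dropped with a warning.

Two conventions are deliberately parameterised:

- **Normalization.** "Normalized SD" is ambiguous; the default mode
  `"mean"` divides the residual SD by the voxel's temporal mean of the raw
  series (a coefficient of variation, invariant to arbitrary scanner
  intensity scaling); `"raw"` returns the plain SD.
- **SD denominator.** `ddof=0` (population convention) by default, so a
  residual alternating ±1 has RSFA exactly 1; the sample convention is one
  keyword away.  The generator and estimator share the convention, so
  round-trip recovery is exact either way.

## Cardiovascular health factors

The seven measures (mean HR, LF- and HF-HRV power, systolic/diastolic BP,
WMH volume, BMI) are screened with a one-sample Kolmogorov–Smirnov test
against a normal with the sample mean and SD (no Lilliefors correction —
matching the cited tool's default, at the cost of a conservative screen);
variables failing at p < 0.05 are log-transformed (they must be strictly
positive) and re-tested.  In practice only WMH, whose marginal is
log-normal, is transformed.

Extraction is a maximum-likelihood common-factor model on the standardized
variables (via `statsmodels`' `Factor`), varimax-rotated, with regression
-method scores standardized to mean 0, SD 1; PCA extraction is available as
a flag because the source description is ambiguous about it.  Factors are
ordered by explained variance and sign-fixed so each factor's
largest-|loading| variable loads positively.  Heywood cases are clamped at
a uniqueness floor of 1e-3 with a warning.  The number of factors defaults
to a fixed k = 3; the Kaiser rule (correlation eigenvalues > 1, with a
1e-8 float guard) is available for data-driven selection.

## Group spatial ICA

Each modality's subjects × voxels matrix is decomposed with subjects as
observations and voxels as variables (the source-based-morphometry
convention): FastICA (log-cosh contrast, tol 1e-6, max 1000 iterations)
runs on the transposed matrix so independence is sought across voxels,
after PCA reduction to an order chosen by the eigenvalue-based MDL
criterion,

    MDL(k) = −N(p−k)·log(geo-mean/arith-mean of the p−k smallest λ)
             + ½·k(2p−k+1)·log N,

with N = number of voxels, p = subjects, candidates k = 1..rank−1.  No
i.i.d.-subsampling ("smoothness") correction is applied: the synthetic maps
have no fMRI-like spatial autocorrelation, so the plain criterion is the
consistent choice.  Zero eigenvalues from exact linear dependencies are
excluded, which keeps the criterion invariant to duplicating subjects.

The decomposition restarts from 5 seeded initializations and keeps the run
with the best negentropy objective; sources are unit-norm rows, sign-fixed
to positive skewness, ordered by explained variance, and the standardized
mixing loadings (`loadings_z_`) are the subject-level summary measures.
`mixing @ sources + mean` reproduces the rank-k PCA approximation of the
input to ~1e-6 relative error.

## Distribution-shape permutation test

Beyond voxel-wise FDR, the package asks whether the *distribution* of
age–residual correlations across voxels differs from chance.  P subject
permutations of the RSFA matrix (one joint row permutation per iteration,
shared across voxels, so each null draw keeps the spatial correlation of
voxels) are pushed through the unchanged stage-one design, giving P+1
correlation distributions.  Medians and shapes of observed vs pooled
permuted correlations are compared by Wilcoxon rank-sum and two-sample KS.
Pairwise KS statistics between all P+1 distributions give each distribution
a similarity profile; Np counts the permuted profiles from which the
observed profile differs (rank-sum at α = 0.05, uncorrected).

The reported significance level is `1 − Np/(P+1)`.  The direction matters:
an observed distribution unlike its permutation null is far from *every*
permuted draw, so Np → P and the complement → 0.  Simulation confirms the
calibration: under a fully null generator the complement's lower 5% tail
fires at ~α, and under a variance-×5 shape difference Np/(P+1) reaches its
maximum.  (Counting Np itself as the significance level would invert the
test.)  Both the raw ratio and the complement are stored.  Defaults:
P = 199 at desk scale; the full-scale 4999 is a config value.  Inside
permutations the first stage is refit by OLS for speed (the design is
fixed; only RSFA rows are permuted) unless `robust_in_permutations` is set.
The whole procedure repeats per tissue class (probability > 0.4, or exact
synthetic labels) and for the whole brain, yielding the model-by-tissue
table.

## The synthetic cohort

The generator realises exactly the causal structure the analysis assumes,
so it is a ground truth for mediation recovery, not a realistic brain
simulator.

- **Subjects.** Age uniform on [18, 88].  Three latent factors are planted
  with *exact sample* correlations to age — the Gaussian noise component is
  residualised against age and orthonormalised before Cholesky mixing — at
  the default targets (+0.061 blood pressure, −0.417 heart-rate/HRV, +0.713
  WMH-risk).  Exact planting removes Monte-Carlo slack from calibration
  checks at any n; an infeasible (non-PSD) target matrix is rejected, not
  repaired.  The seven measures are linear mixtures of the factors (fixed
  loading matrix with communalities 0.27–0.72, chosen so the third factor's
  population eigenvalue exceeds the Kaiser threshold) plus unique noise,
  scaled to physiological units; WMH is exponentiated so its marginal is
  log-normal and exercises the transform rule.
- **Maps.** Smooth Gaussian blob sources (σ = min(grid)/9, unit norm,
  centres ≥ 3.5σ apart giving pairwise |cosine| ≈ 0.05 and support overlap
  ~11%) are shared across modalities; mediation is planted at the
  component-loading level (CBF ← age; GMV ← age + CVH; RSFA ← CVH + CBF +
  optional direct age path) and projected to voxels with isotropic noise.
  Each source has a dominant tissue class (cycling GM/WM/CSF); per-voxel
  labels follow the strongest source.
- **BOLD.** Series are baseline + white noise projected onto the in-band
  DCT space — the same projector the estimator uses, so target amplitudes
  are attainable exactly — rescaled per voxel to the target RSFA, plus
  motion-locked drift (spanned by the realignment parameters) and global
  WM/CSF signals weighted by tissue probability.

Not emulated: hemodynamic response functions, MR physics, realistic spatial
autocorrelation, motion image artifacts, or non-Gaussian physiological
noise.  Passing tests therefore demonstrate that the *statistical
machinery* recovers the assumed structure, not that the assumptions hold in
real data.

Default problem sizes — 250 subjects, 16³ = 4096 voxels, 4 sources,
P = 199 permutations, 20-cohort replications, 100-run calibration at
P = 99 / 500 voxels / 60 subjects — were chosen as the smallest scales at
which the planted effects and the sampling-error bounds quoted in the tests
are comfortably separated.

## Known limitations

- The KS normality screen with estimated parameters (no Lilliefors
  correction) is conservative; borderline non-normal variables may pass.
- Varimax factors are a rotation of the planted obliquely-age-correlated
  factors, so the *estimated* factor–age correlations are attenuated
  relative to the planted ones (e.g. ~0.6 recovered for a 0.71 target);
  congruence, not correlation equality, is the recovery criterion.
- MDL order selection is reliable for well-separated sources but, like any
  eigenvalue criterion, undercounts when loadings noise approaches source
  scale.
- The permutation decision is conservative under the null (empirical type-I
  ≈ 0.02 at α = 0.05) because rank-sum comparisons between correlated
  similarity profiles are not exchangeable in the strict sense.
- Subject alignment is by id join with a strict-mismatch error; no
  resampling across voxel grids is performed anywhere.
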