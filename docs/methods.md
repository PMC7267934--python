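# Methods

## Model

`tractsem` implements a hierarchical (watershed-style) MIMIC structural
equation model. Observed exogenous causes `x` — the mean tract-based
fractional anisotropy (mTBFA) of ten major white-matter fascicles plus age
— act on two latent variables, fluid (FI) and crystallized (CI)
intelligence, which produce the four observed WAIS-III index scores:

```
η = Γ x + ζ,   ζ ~ N(0, Ψ)          (structural layer, Ψ full symmetric)
y = Λ η + ε,   ε ~ N(0, Θ)          (congeneric measurement, Θ diagonal)
```

Assumptions: linearity, multivariate normality for likelihood-based
inference (with the Satorra–Bentler factor reported as a kurtosis
diagnostic), congeneric measurement (each index loads on exactly one
latent), and exogeneity of the tract/age block. Means are not modeled;
everything operates on centered data at the covariance level.

### Identification and degrees of freedom

Marker identification (first listed indicator's loading fixed at 1 per
latent) is the default; unit-variance identification is available. The
exogenous covariance Φ is fixed at the sample covariance of the predictors
(conditional-on-x formulation). Consequently predictor-only moments and Φ
entries are excluded from both the moment count and the free-parameter
count, so df = p(p+1)/2 + p·q − n_free. This reproduces the standard CFA
counts (one-factor on four indices: df 2; two correlated factors: df 1)
and keeps MIMIC df well defined. Whether the original analysis estimated
or fixed the exogenous covariances is not documented; a free-Φ mode exists
for sensitivity checks, in which all m(m+1)/2 moments and Φ parameters are
counted.

### Estimation

The normal-theory discrepancy `F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − m` is
minimized by L-BFGS-B on a transformed parameter vector: variances (Θ, Ψ
and Φ diagonals) live on the log scale, which enforces positivity without
inequality constraints; loadings, regressions and covariances are raw.
Gradients are analytic (matrix chain rule on the implied-covariance
blocks, verified against finite differences in the tests). After L-BFGS a
damped Newton polish — Hessian from central differences of the analytic
gradient — removes the last order of magnitude of gradient norm.
Convergence requires a projected-gradient ∞-norm below 1e−7 within 500
iterations; components pressing into an active bound are excluded, so a
solution pinned at the variance floor (a Heywood case, flagged on the
result) still counts as converged. Start values: each marker's observed
variance split 50/50 between latent disturbance and residual, other
loadings from covariances with the marker, Γ = 0. Two jittered restarts
guard against bad starts. Sample covariances use divisor N−1, paired with
the χ² multiplier (N−1)·F_ML; the N·F_ML convention is available since the
original software's choice is not documented.

Boundary solutions are genuine here, not optimizer failure: with only two
indicators per factor the loading/residual split is weakly determined, and
at N ≈ 1000 a residual variance occasionally hits zero (confirmed by
Nelder–Mead and multi-start agreement on the same minimum).

### Fit battery

* χ², p from the central χ² upper tail (df from the counting rule above).
* RMSEA √(max(χ²−df,0)/(df(N−1))) with the 90% interval from the
  noncentral-χ² coverage equations (Brent root search, truncated at 0);
  undefined (error) at df = 0.
* CFI against the independence baseline: indicators mutually uncorrelated
  and uncorrelated with predictors, predictor block untouched. The
  baseline is expressed in the same model machinery (one latent per
  indicator, loading fixed at 1, diagonal disturbances, residuals fixed at
  zero).
* SRMR: RMS of standardized residuals over the lower triangle including
  the diagonal, each matrix standardized by its own diagonal.
* BIC = −2·loglik + k·ln N with the full multivariate-normal
  log-likelihood (ML covariance divisor N inside the likelihood).
* Satorra–Bentler c = tr(UΓ_N)/df with Γ_N the empirical asymptotic
  covariance of vech(S) (fourth-order moments, divisor N), W the
  normal-theory weight at the estimate, and U the residual weight after
  projecting out the model derivative space Δ. With Φ fixed at the sample
  covariance, the Φ entries are appended to Δ as estimated quantities so
  that U's rank matches the conditional df. Unscaled χ²/RMSEA/CFI are
  reported with c alongside, never robust-scaled versions.
* Indicator R² = 1 − Θᵢᵢ/Σ̂ᵢᵢ.

A note on reported study values: the printed one-factor RMSEA of 0.161
(χ²=5.589, df=2, N=83) is not reproducible from the standard definition
under either χ² multiplier (which give 0.147–0.148); it is likely a robust
variant. The implementation keeps the standard formula.

### Elastic-net penalized path

The penalized objective is `F_ML + λ Σⱼ(α|γⱼ| + (1−α)γⱼ²)` over the
penalized structural coefficients (all 22 tract/age → latent edges by
default; age can be exempted). Defaults: α = 0.5 (equal lasso/ridge mix)
and a grid of 35 equally spaced λ from 0 to 0.35. Because the penalty is
not scale invariant, path fitting standardizes all observed variables
internally (fit on the correlation matrix); coefficients are reported on
that scale and back-transformed via sd(marker)/sd(predictor) for the raw
scale.

Optimization folds the smooth ridge term into the objective and treats
only the λα|γ| part proximally: a FISTA sweep (adaptive step, momentum
restart) identifies the active set with exact zeros, then an
orthant-constrained L-BFGS polish refines smooth and surviving penalized
coordinates together, with KKT checks (|∂F/∂γ| ≤ λα at zeros) reactivating
any violating coordinate. Fits are warm-started along the grid; λ = 0
falls back to the smooth ML path and reproduces `fit_ml` exactly. After
convergence at λ > 0, penalized estimates below 1e−3 in magnitude are set
to exactly zero and the non-penalized block is refit once with those
pinned.

Selection minimizes `bic_reg = (N−1)·F_ML + k·ln N`, where k counts free
non-penalized parameters plus surviving nonzero penalized ones; ties break
toward the largest λ (the sparser model). The per-observation-scale BIC
printed by the original R tooling (0.836) follows an undocumented
convention and is deliberately not chased.

**Known limitation — support over-selection.** At the study-default
conditions (N = 1000, standardized true effects ±0.3, exchangeable tract
correlation 0.3), the selected model reliably contains the true edges but
usually carries 1–5 small spurious ones. This is a property of the
procedure, not the optimizer (KKT residuals are ~1e−8 at every grid
point): the ML sampling noise of a null structural coefficient has
standard error ≈ 0.033, so the largest of 18 null edges is ≈ 0.09–0.10,
while the curvature of F_ML per standardized coordinate is
≈ 2/((N−1)·se²) ≈ 1.7 — zeroing the largest null edge therefore needs
λα ≳ 0.17, the very top of the grid, before shrinkage of the true
coefficients leaks compensating gradient into their correlated neighbours.
Meanwhile bic_reg, evaluated at the shrunken estimates, charges roughly
ln N of extra discrepancy per true edge for the additional shrinkage a
larger λ causes, so the minimum lands mid-grid with stragglers attached.
Exact support recovery becomes reliable only with weaker noise (N ≳ 4000)
or a longer grid; at the study scale the method should be read as
screening in the true edges, not as a consistent support estimator.

## Tractography

FACT (Fiber Assignment by Continuous Tracking) with voxel-constant
directions and exit-face stepping, no interpolation: within a voxel the
fiber follows that voxel's principal eigenvector (sign aligned with the
incoming heading), crosses into the neighbour the ray exits into, and
records visited voxels. Termination: entering a voxel with FA < 0.10 or
trace > 0.002 mm²/s (the offending voxel is not kept), a turn between
successive voxel directions exceeding 53.1°, leaving the grid, or
revisiting a voxel (loop guard). Tracking starts only at voxels with
FA ≥ 0.15 and trace ≤ 0.0016, runs bidirectionally from the seed, and
discards results visiting fewer than 5 voxels. How the original toolbox
interpolated directions or measured the turning angle is not documented;
this variant is documented, not claimed identical.

Brute-force reconstruction seeds every qualifying voxel (lexicographic
order, duplicate voxel-sequences removed), multi-ROI selection keeps
streamlines visiting every inclusion ROI and no exclusion ROI, and mTBFA
is the mean FA over the union of visited voxels ("superposition" read as
an unweighted union; a visit-count-weighted option exists since the
original description does not specify). Bilateral tracts are averaged
arithmetically; a missing hemisphere passes through with a warning. The
manual visual pruning of anatomically implausible fibers in the original
workflow is replaced by explicit exclusion-ROI masks — reproducibility
over fidelity. Coordinates are 0-based voxel indices; NIfTI tensor volumes
store 6 lower-triangular components in (xx, yx, yy, zx, zy, zz) order;
masks and maps must share the grid (no resampling — registration is out of
scope, as is tensor fitting from raw diffusion images).

## Synthetic data

The subject-table generator draws the 10 FA predictors as exchangeably
correlated standard normals (ρ = 0.3, a plausible adult-tract value; the
source reports no predictor moments), age from a truncated normal
(pre-truncation location 35.03, scale 10.27 years, range 18–69),
independent of the FA block. Latents have unit population variance:
disturbance variances are 1 − Var(Γx) and the two disturbances correlate
at 0.4 (a moderate FI–CI residual association; chosen once as a
documented default). Loadings and residuals are calibrated analytically so
each indicator's population R² equals its target (0.856, 0.408, 0.756,
0.483 for PO, PS, VC, WM): with unit latent and indicator variances,
λᵢ = √R²ᵢ and Θᵢᵢ = 1 − R²ᵢ — an exact closed form, checked without
simulation. The default sparse truth uses standardized effects of
magnitude 0.3 (age→FI +, age→CI −, Fmn→CI +, SLF→FI −); the study's
printed unstandardized coefficients are too scale-ambiguous to serve as
simulation truth. Output columns are rescaled for realism (FA 0.45 ± 0.03,
indices at their published means/SDs); the analysis standardizes
internally, and fit statistics are scale-equivariant, so this is cosmetic.
Generators are pure functions of (config, seed).

Phantoms place prolate tensors (closed-form axial/radial eigenvalues for a
requested FA and trace) along polyline bundle paths inside a background
that fails the start criteria (FA 0.05, trace 0.0021), with two inclusion
ROIs per bundle at 25% and 75% of arc length and ground-truth mTBFA
recorded before optional tensor noise (PSD restored by eigenvalue
clipping). Overlapping bundles with tangents more than ~18° apart raise
unless a crossing is explicitly requested. The end-to-end generator
replaces chosen FA columns of the subject table with values extracted by
actually tracking per-subject phantoms whose bundle FA is the subject's
simulated value; on noise-free phantoms extraction is exact to machine
precision, which ties the imaging front end to the SEM back end without
claiming realism.

What these simulations do not emulate: DWI signal formation (b-vectors,
Rician noise), partial-volume mixtures, crossing-fiber ambiguity within a
voxel, registration error, or demographic confounding beyond age. Passing
tests therefore validate the algorithms and their numerics, not the
field-data behaviour of the full imaging pipeline.

## Problem sizes and numerical choices

Tests and the acceptance script use: N = 10⁵ for calibration and parameter
recovery (bias < 0.02), N = 1000 × 20 replicates for support recovery,
50 replicates × N = 5000 for the Satorra–Bentler means, 500 replicates ×
N = 500 for the χ² type-I-error check, and phantom grids of ~2000–4000
voxels — sizes at which every result above is stable on a single CPU in
minutes. Tolerances: optimizer gradient 1e−7; FISTA step tolerance 1e−8;
sparsification 1e−3; rotation-invariance assertions 1e−10; ML parameter
agreement at λ = 0 to 1e−6. Degenerate inputs are explicit errors:
zero-variance columns (relative tolerance 1e−12), non-PD implied
covariance (no silent ridging), df = 0 RMSEA/Satorra–Bentler, empty
tracts, empty inclusion-ROI lists.
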