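# Methods

This note documents the statistical model, the estimation machinery,
the synthetic-data generator and the numerical choices behind
`arboreml`, at the level of detail a user needs to judge what a fitted
number means and what the test suite does and does not demonstrate.

## Model

One trait at a time, over one or several trials:

    y = Xβ + Σ_k Z_k u_k + e,   u_k ~ N(0, σ²_k G_k)

* **Fixed effects** `β`. For the post hoc models: an intercept, trial
  main effects, and the row (x) and column (y) grid coordinates as
  numeric covariates with a separate slope per trial (centred within
  trial for conditioning). Optionally the 0–4 competition index (a
  5-level factor per trial by default; a numeric-covariate switch
  exists because the index is ordinal) and the distance principal
  components PC1–PC3, again with per-trial coefficients. The RCBD
  baseline has an intercept only. Rank-deficient columns are detected
  by pivoted QR and dropped with a warning; the retained rank defines
  the residual degrees of freedom `v = n − rank(X)`.
* **Additive genetic effects** with level covariance A, the numerator
  relationship matrix from the pedigree (tabular recursion; unknown
  parents are unrelated founders). For the open-pollinated layout —
  every phenotyped tree the offspring of a founder dam and an unknown,
  unrelated sire — the observed-tree block of A is exactly
  `0.75·I + 0.25·FF'` (F = family incidence), which the engine uses as
  a diagonal-plus-low-rank factorisation; arbitrary pedigrees fall back
  to a dense Cholesky factor of the observed submatrix. Treating
  open-pollinated sibs as exact half-sibs is an assumption: correlated
  paternity or relatedness among dams would inflate σ²_A.
* **Family-by-trial interaction** (`σ²_AE`) with identity level
  covariance — the interaction levels are independent across trials,
  matching the usual "simple" G×E parameterisation.
* **Design factors**: replicate-in-trial, plus the scheme's row and
  column blocks (incomplete bands or complete tiers) nested in trial.
  The RCBD baseline instead carries trial-in-series, series and
  provenance as random terms.
* **Residual**: per trial, a separable first-order autoregressive field
  plus an independent nugget,
  `R_t = σ²_ε (Σ_row ⊗ Σ_col)|obs + σ²_e,t I`, restricted to observed
  cells (missing positions are dropped, never imputed). Three kinds:
  `iid_simple` (no AR1), `ar1_plus_iid` (shared nugget) and
  `ar1_plus_hetero` (trial-specific nuggets). The spatial parameters
  (σ²_ε, ρ_row, ρ_col) are per-trial by default — each trial has its
  own grid and micro-climate — with a shared-parameter option for
  parsimony and for simulation studies whose truth is a single field.

Phenotypic variance for parameter reporting is deliberately
`σ²_P = σ²_A + σ²_AE + σ²_E` — design variances (rep, row, col) and the
spatially structured σ²_ε are *excluded*, because they are properties
of the trial, not of the trait. For heterogeneous residuals σ²_E is the
unweighted among-trial mean of the nuggets.

### Derived genetic parameters

* `h² = σ²_A/σ²_P`, `r_B = σ²_A/(σ²_A + σ²_AE)`.
* Coefficients of variation divide the **variance** component by the
  trait mean (×100). This follows the convention of the analyses this
  package reproduces; it is not the textbook `100·sd/mean`, which is
  available behind `use_sd=True`. Values above 100% are therefore
  possible and expected for high-variance traits.
* Breeding-value accuracy `r_i = √(1 − PEV_i/((1+f_i)σ²_A))`, clipped
  to zero when the prediction error variance exceeds the prior.
* Standard errors of any smooth function of the variance parameters use
  the delta method: a central-difference gradient (step
  `1e-5·(|θ|+1e-8)`) against the REML asymptotic covariance. If a
  parameter involved sits on the zero boundary the SE is reported
  unavailable (NaN) rather than as a misleading number.

## Estimation

Variance parameters maximise the restricted log-likelihood

    logL_R = −½ [ log|V| + log|X'V⁻¹X| + y'Py ]

(the constant `−(n−p)/2·log 2π` is omitted throughout; AIC/BIC
comparisons are unaffected). The engine is an average-information (AI)
REML: Newton-type steps with `AI_jk = ½(Py)'V̇_j P V̇_k(Py)` and the
analytic score, safeguarded so the likelihood never decreases
(step-halving, Levenberg damping of the AI matrix on failure). Because
AI steps converge only linearly along flat ridges (notably the
σ²_ε/σ²_e split), successive gain ratios are monitored and the step is
geometrically extrapolated by `1/(1−r)` (capped at 16) when the decay
is stable — this typically cuts the iteration count by half or more
without affecting the optimum.

Every random term enters V as `γ(c·I + UU')`; the diagonal parts merge
with the residual into a block-diagonal-by-trial matrix D, and V is
handled through the Woodbury identity with one dense Cholesky per trial
block plus a q×q system over all low-rank columns. At the package's
design scale (a few thousand trees, trials of ≤ ~1,500 cells) one
likelihood evaluation costs a few hundred milliseconds and a full fit
seconds to tens of seconds on one core.

Constraints: variances ≥ 0, |ρ| ≤ 0.98. A variance pressed to zero
with a negative score is pinned there and flagged as a boundary
estimate (reported as `0` with SE unavailable); its AR1 correlations
are pinned with it, since they are unidentified once σ²_ε = 0, and
pinned parameters are released if their score turns positive later.
Convergence requires the likelihood gain and the relative parameter
change to drop below 1e-6 (a likelihood gain at the 1e-9 numerical
noise floor also counts, because parameters can drift indefinitely
along exactly flat directions); non-convergence within 200 iterations
is reported through `converged=False`, never raised. Starting values
split the OLS residual variance equally across variance parameters,
with ρ = 0.1.

The asymptotic parameter covariance is the inverse AI matrix over the
free (non-boundary) parameters at the optimum; the 50-replicate
recovery experiment in the acceptance suite checks its calibration
(±2 SE coverage ≥ 90% per parameter at the default scenario).

BLUE/BLUP/PEV solve Henderson's mixed-model equations at the REML
estimates: coefficient matrix `W'R⁻¹W + blockdiag(0, G_k⁻¹/σ²_k)`,
prediction-error variances from the inverse diagonal. The additive
block uses the sparse pedigree inverse of A over *all* pedigree
members, so dams without own records get breeding values and PEVs; for
a collapsed half-sib term without a pedigree system the Mendelian
diagonal folds into R and the low-rank coefficients are the dam
breeding values directly (the two routes agree, and are tested against
dense GLS/conditional-expectation formulas). Terms at the zero boundary
contribute BLUPs of exactly zero. Model comparison uses
`AIC = 2t − 2·logL_R` and `BIC = t·ln(v) − 2·logL_R` with `t` = the
number of variance parameters of the model (boundary estimates are
still counted — they were estimated) and `v = n − rank(X)`; suite
reports show deltas against the complete-blocking benchmark, which is
zero by construction for the benchmark itself.

## Post hoc geometry and spatial covariates

The complete grid (including dead, missing and filler positions) is
rebuilt from the records; fillers occupy cells and compete but carry no
phenotype. Complete blocking cuts rows and columns into contiguous
tiers whose widths differ by at most one cell. Incomplete sub-blocking
tiles the grid with `block_rows × block_cols` rectangles (default 5×5,
the published configurations being presets of the same mechanism);
remainder cells fold into the last band along each axis so no band is
smaller than the nominal size — consequently the band count is
`floor(n/size)`, not `ceil`. Both the row and column bands enter the
model, not the rectangle intersection.

The distance matrix covers *all* grid cells (the AR1 field and the PCs
are properties of position, not of survival); PC scores are
column-centred, unscaled, with each component's loading sum made
nonnegative so results are reproducible bit-for-bit, and are joined to
measured trees only. On trial-scale grids PC1–3 capture ≈ 96.5–98.4%
of the distance variance (verified independently against R `prcomp` on
all six published grid shapes; published prose rounds this to
"98–100%"). The competition index counts *living* stems (measured or
filler) within one spacing unit — dead neighbours exert no competition
— giving the rook-neighbour count 0–4.

## Synthetic data generator

The generator is the package's testbed and encodes the study
conditions as defaults: four trials in two series (grids 40×30, 30×48,
20×60, 25×30), 30 complete blocks per trial tiled as the squarest
factorisation of 30 for the grid's aspect ratio, single-tree plots with
one tree per family per block and leftover cells as fillers, 32 and 34
families per series sharing 21 (52 dams), and height-scale variances
σ²_A = 0.4, σ²_AE = 0.2, σ²_rep = 0.4, σ²_row = σ²_col = 0.2,
σ²_ε = 0.5, ρ_row = ρ_col = 0.5, σ²_e = 2.0, mortality 0.25. Truth
components are stored per tree and sum to the phenotype exactly.

Choices worth knowing about:

* The AR1 field is drawn by the per-axis Cholesky factorisation
  (`√σ²_ε · L_r E L_c'`), one shared (ρ_row, ρ_col) across trials — the
  generator's truth is a single field law, so the recovery harness fits
  the shared-spatial model variant to keep truth and model aligned.
* Row/column environmental effects are generated on the default 5-cell
  incomplete bands, making the sub-blocking models correctly specified
  for simulated data. Real trials have no such alignment; passing
  recovery tests show the estimator works when its assumptions hold,
  not that 5×5 is the right band size for a given field.
* Mortality is spatially uniform Bernoulli by default (a clustered
  option exists for stress tests). A simulated tree whose height comes
  out non-positive (a ≈1e-4 Gaussian-tail event at the default means)
  is recorded as dead rather than emitting an impossible phenotype.
* Competition class effects are injectable per neighbour count but
  default to zero: the generator's contract is the statistical
  structure the analysis assumes, and a nonzero default would place
  truth outside every model lacking the competition covariate.
* DBH is a crude allometric function of height plus noise — enough to
  exercise the volume/DBH code paths, with no claim of biological
  realism; survival carries no genetic signal under uniform mortality.

The recovery harness simulates `n_seeds` replicates (~3,000 measured
trees each at the defaults), refits the chosen model, and reports per
parameter the mean estimate, empirical SD, mean reported SE and ±2 SE
coverage. The acceptance suite runs it with 50 replicates of the SUBB
model; runtime is roughly 10 minutes on one core, by far the largest
item in the test budget.

## Known limitations

* Survival is analysed on the observed 0/1 scale with the Gaussian
  machinery (as in the analyses this package mirrors); a threshold or
  logistic model would be more defensible near the extremes.
* Single-trait analyses only; no genetic correlations between traits,
  no genomic relationship matrices, no dominance.
* The AI asymptotic covariance is a large-sample approximation;
  near-boundary parameters have asymmetric uncertainty it cannot
  express.
* Dense per-trial linear algebra bounds practical problem size to a few
  thousand observations per fit — ample for the progeny-trial scale it
  targets, unsuitable for national-evaluation scale.
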