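# Methods

## The twin model

Each twin pair contributes one multivariate normal observation. For a
single trait the pair vector `(y1, y2)` has mean `X β` (intercept, age
and sex, both centered; sex coded male = 1) and covariance

```
Var(y_i)      = a² + c² + e²
Cov(y1, y2)   = a² + c²        (MZ pairs)
              = a²/2 + c²      (DZ pairs)
```

where `a²`, `c²`, `e²` are the additive-genetic, common-environment and
unique-environment variance components. Heritability is
`H² = a²/(a² + c² + e²)`. The AE and CE submodels fix `c² = 0` and
`a² = 0` respectively. The unstructured model replaces the ACE
structure with a common variance and free within-pair correlations
`r_MZ`, `r_DZ` (Fisher-z parameterized); it is the saturated
covariance model of the ACE family and is used as an exploratory
companion.

The multivariate model stacks p traits per twin into a 2p-vector with
within-twin block `P = A + C + E` and cross-twin block `A + C` (MZ) or
`A/2 + C` (DZ), where A, C, E are p×p matrices. From a fitted model the
package reports genetic correlations `r_g = A_jk/√(A_jj A_kk)`,
non-shared correlations `r_e = E_jk/√(E_jj E_kk)`, phenotypic
correlations from P, and the bivariate heritability `A_jk/P_jk` — the
share of a phenotypic covariance carried by additive genetics, which is
deliberately not truncated to [0, 1] (it legitimately exceeds 1 when
genetic and environmental covariances have opposite signs; such entries
carry an instability flag when the phenotypic correlation is near 0).

### Estimation

All models are fitted by full maximum likelihood (not REML): the
log-likelihoods of models with a common mean structure are then
directly comparable, which is what makes the AIC/BIC ladder
(`AIC = −2LL + 2·df`, `BIC = −2LL + df·ln N`) meaningful. Univariate
components are parameterized as squares, so estimates are non-negative
by construction; estimates landing at the zero boundary are flagged
rather than hidden. A second parameterization (`constrain="none"`)
lets components go negative, as covariance-GLM estimators do; it is
mean-unbiased across replicate studies at the cost of occasionally
inadmissible values. Multivariate component matrices use Cholesky
factors, which keeps them positive semidefinite throughout
optimization; because a Cholesky factor of exactly zero is a
stationary point of `L Lᵀ`, fits run from two interior starting points
(moment estimates with eigenvalues floored at 5% of the mean variance,
and an equal split of the phenotypic covariance) and keep the better
optimum. Univariate and p ≤ 2 multivariate fits get a derivative-free
polish pass, so the p = 1 multivariate fit agrees with the univariate
fit to optimizer precision (~1e−6).

Standard errors come from the observed information (numerical Hessian)
with the delta method for variance shares; a zygosity-stratified
pair-resampling bootstrap is provided for boundary cases where the
quadratic approximation is unreliable.

### Known finite-sample behaviour

With 43 MZ but only 14 DZ pairs, the A-versus-C split is weakly
identified. Replicate-study calibration (`twinpk.calibration`) shows
that the constrained ML estimator recovers a generating heritability of
73% with mean ≈ 71% (SD ≈ 22 points), while a generating
common-environment share of 48% is recovered with mean ≈ 41%
(SD ≈ 23 points): ML covariance estimates based on 14 pairs are
differentially biased low, which deflates `c² ≈ 2w_DZ − w_MZ`, and the
share's ratio nonlinearity adds to the effect. The unconstrained
variant is unbiased in the raw components at large n (verified at 10×
the design size) but not in the shares at this n. These are properties
of the design, not of the implementation; the calibration module exists
to make them measurable.

## Non-compartmental analysis

* **AUC** uses the linear-up/log-down trapezoidal rule: linear on
  rising/flat segments, logarithmic on strictly declining segments with
  positive endpoints, linear fallback at zeros; interval endpoints
  falling between samples are interpolated with the same segment rule.
* **λz** is the slope of a log-linear regression over the terminal
  tail. All candidate tails of ≥ 3 positive samples strictly after
  Cmax (Cmax excluded) compete on adjusted R², ties broken toward more
  points; flat tails and non-declining fits are rejected with explicit
  errors.
* **AUC_∞** adds `Ĉ(t_last)/λz` to AUC_last, with the last
  concentration predicted from the λz regression rather than observed —
  less sensitive to assay noise in the final sample.
* **Infusion-end anchor.** The study's first post-dose sample is drawn
  at 15 min, after a 2-min infusion, so the trapezoid from 0 to 15 min
  clips the infusion peak and biases AUC ~3% low. For the parent drug
  the package inserts a virtual sample at the end of infusion,
  log-linearly back-extrapolated from the first two declining samples
  (exact for mono-exponential decay). Cmax, tmax and λz always use
  observed samples only. The anchor is on by default in the table-level
  API and can be disabled.
* **AUC_420** is computed to 420 min, a scheduled sample on the default
  grid; for irregular grids the interpolation above applies.
* Clearance is `dose/AUC_∞` (µg over µg·min/L gives L/min);
  per-kilogram clearance uses total body weight. Lean body weight
  appears only in the covariate models.
* Below-limit samples can be flagged; they are excluded from the λz
  regression.

## The synthetic-data generator

The generator is first-class, tested code: it defines the conditions
under which every estimator is validated.

* **Design defaults**: 43 MZ + 14 DZ same-sex pairs (the analysed
  cohort; the enrolled 44 MZ pairs are available by config), 200 µg
  midazolam over 2 min, samples at 0, 15, 30, 45, 60, 90, 120, 150,
  180, 240, 300, 360, 420, 480 and 1440 min, three occasions.
* **Latent traits** live on the natural-log scale (PK parameters and
  biomarkers are positive and right-skewed). Per pair, additive draws
  correlate 1.0 (MZ) or 0.5 (DZ, built from a shared and an own
  standard-normal via `(z_s + z_i)/√2`), common-environment draws are
  shared, unique draws are independent — giving the ACE covariance
  structure exactly, not asymptotically.
* **Default A, C, E matrices** (4 traits) assemble published univariate
  variance shares (15/48/37, 73/21/6, 56/22/22, 31/36/33 percent for
  midazolam AUC, 1-OH-midazolam AUC, 4ß-OH-cholesterol,
  6ß-OH-cortisol) with total log-variances derived from the observed
  between-subject CVs (`ln(1 + Var_b/mean²)`: 0.051, 0.313, 0.121,
  0.152), genetic/non-shared off-diagonals from the published `r_g` and
  `r_e`, and C off-diagonals chosen to reproduce the published
  phenotypic correlations. Any non-PSD result would be projected by
  eigenvalue clipping (the defaults happen to be PSD already, so the
  published structure is reproduced exactly).
* **PK model**: one-compartment, zero-order infusion;
  `C(t) = (R₀/CL)(1 − e^{−kt})` during infusion, mono-exponential decay
  after, with `k` fixed by a nominal 163-min half-life (the observed
  median) and V derived as `CL/k`. The subject's clearance is
  `dose/AUC` from the latent log-AUC. The 1-OH-midazolam profile solves
  the linear metabolite ODE in closed form with formation fraction
  0.75 (the reported share of midazolam eliminated via
  1-hydroxylation) and a nominal 60-min metabolite half-life; its
  clearance is set from the latent metabolite AUC so that
  `AUC_m = f_m·dose/CL_m` holds analytically.
* **Noise structure**: the occasion effect is a mean-one lognormal
  multiplier on clearance (CV 11.3% parent, 12.3% metabolite — the
  observed within-subject AUC variation), so within-subject AUC
  variation has the right structure; assay noise (CV 5%, a typical
  LC-MS/MS figure) is multiplicative per sample and largely averages
  out of AUC.
* **Endogenous biomarkers**: `exp(latent) ×` mean-one lognormal
  occasion noise with CVs 14.6% (4ß-OH-cholesterol) and 29.4%
  (6ß-OH-cortisol), back-calculated from the published within-subject
  variances. An autocorrelation parameter ρ splits the occasion
  deviation into a subject-constant and an occasion-specific part;
  ρ → 1 reproduces the almost-frozen occasion profile expected of a
  biomarker with a ~60-h half-life (default 0: the published
  within-subject variances already absorb this).
* **Genotypes**: variant-allele copy numbers with frequencies 0.018
  (CYP3A4\*22) and 0.07 (active CYP3A5\*1), matching the observed 4
  heterozygous \*22 carriers and 16 CYP3A5 expressors in 114 subjects.
  MZ twins copy genotypes; DZ twins inherit from two simulated parents
  (Mendelian sibling sharing, correlation 0.5). Default mean-structure
  effects plant a +35% \*22 effect on midazolam AUC and a +33%
  CYP3A5\*1 effect on 4ß-OH-cholesterol (log-scale per-allele
  coefficients from the published median contrasts); age/sex effects
  default to zero and are configurable.
* **What it does not emulate**: liver blood flow and its physiology,
  circadian cortisol rhythms, BLQ censoring, assay drift, dropout, and
  real demographic covariance (height/weight are drawn from simple
  sex-conditional normals). Passing tests therefore demonstrate
  estimator correctness under the declared generating process, not
  robustness to every feature of real bioanalytical data.

## Repeatability

`Var_w` pools per-subject sample variances weighted by degrees of
freedom; `Var_b` is the sample variance of subject means, deliberately
without subtracting `Var_w/k` (this plain form reproduces the published
1-OH-midazolam genetic component exactly; the corrected form is an
option). `rGC = (Var_b − Var_w)/Var_b` may be negative and is reported
as computed. Applying the formula to the published variance table
reproduces the 1-OH-midazolam value (0.9325 vs printed 0.931) but not
the midazolam value (0.595 vs printed 0.612; the original computation,
possibly on unrounded or day-wise data, cannot be reconstructed) — this
is documented rather than guessed at.

## Covariate and genotype models

One joint OLS regression per biomarker (log scale by default) on sex,
age, lean body weight, smoking, contraceptive use and genotype copy
numbers. Twins are not independent, so the default inference uses
cluster-robust covariance by pair (the naïve option is retained for
comparison). Per-factor `partial_r2` is the squared semi-partial
correlation (drop in R² when the factor is removed); collinear factors
are dropped with a printed warning. Lean body weight uses the
Hume-type sex-specific linear formula
(`LBW = 0.32810·W + 0.33929·H_cm − 29.5336` for men,
`0.29569·W + 0.41813·H_cm − 43.2933` for women; overridable).
Genotype contrasts compare group medians with a Mann–Whitney test;
CYP3A4\*1B is grouped with \*1. The diet analysis is an ordinal
Spearman trend test and is explicitly exploratory.

## Numerical choices

* Optimizers: L-BFGS-B with tight tolerances, Nelder-Mead polish for
  low-dimensional problems (univariate, p ≤ 2 multivariate).
* Degenerate inputs fail loudly: empty cohorts, non-PSD component
  matrices (the offending matrix is named), single-occasion
  repeatability, zero between-subject variance, flat concentration
  profiles, empty genotype groups.
* Determinism: all randomness flows from one seed through named
  `SeedSequence` substreams per stage; the pipeline manifest records a
  SHA-256 content hash per artifact, and rerunning with the same
  config and seed reproduces identical hashes.
* Replicate-study sizes in the test suite (200–400 univariate
  replicates, 100 bivariate replicates, 1000 null-calibration
  regressions) were chosen so the Monte-Carlo standard error of each
  checked mean sits well inside the asserted tolerance.

## Limitations

* The variance-share estimators are finite-sample biased at 14 DZ
  pairs (see above); single-study estimates near boundaries are common
  and flagged, not suppressed.
* The multivariate model is practical to ~6 traits; beyond that the
  Cholesky parameter count outgrows twin-pair data.
* Standard errors for the correlation decomposition default to the
  pair bootstrap; no analytic sandwich covariance is provided, and the
  original study's SE convention is not claimed to be matched.
* Dominance (ADE) and sex-limitation models are out of scope, as are
  compartmental PK fitting and urinary pharmacokinetics.
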