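# Methods

## Model and estimation

The package fits cross-species linear models whose errors share a
phylogenetic covariance: `y = Xβ + ε`, `ε ~ MVN(0, σ²V)`. `V` is built from
a rooted tree with branch lengths under one of three structures:

* **Brownian**: `V[i,j]` is the root-to-MRCA depth of the pair, computed by
  one postorder sweep; the diagonal is each tip's root-to-tip depth.
  Non-ultrametric trees are accepted and use raw branch lengths.
* **Pagel's λ**: the Brownian matrix with off-diagonals multiplied by
  `λ ∈ [0,1]`, diagonal untouched. At `λ=1` this equals Brownian exactly;
  at `λ=0` it is diagonal, i.e. phylogeny-free. The upper bound stays at 1;
  positive definiteness is verified numerically at fit time (Cholesky with
  a `1e-10`-scale jitter fallback) rather than derived analytically.
* **Ornstein–Uhlenbeck**: a correlation matrix `exp(−α·d_ij)` of patristic
  distances with unit diagonal (the Martins–Hansen form). The full OU
  stationary-variance parameterization is deliberately not implemented;
  the exponential-correlation form is the standard reading of "OU-based"
  correlation structures in comparative GLS software.

Estimation whitens through the lower Cholesky factor `L` of `V`
(`z = L⁻¹y`, `W = L⁻¹X`) and solves the OLS problem on `(z, W)`; this is
algebraically `β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y` but numerically stable. The package
never inverts `V` directly; the explicit-inverse closed form exists only as
an independent oracle in the test suite.

* `σ̂² = rᵀV⁻¹r / n` (ML). Standard errors scale `σ̂²` by `n/(n−k)` as a
  finite-sample correction, with `k` the number of regression coefficients.
* `logLik = −n/2·log(2πσ̂²) − ½log|V| − n/2`.
* A perfect fit (`σ̂² = 0`) raises an explicit degenerate-fit error instead
  of returning infinite t-values.
* t statistics use `df = n − k` (not further reduced for the estimated
  structure parameter, matching conventional PGLS output); p-values are
  two-sided Student-t. Display rounding prints p to 3 decimals with `0`
  meaning `< 5e-4`; full precision is retained internally and in sidecars.
* `AIC = −2·logLik + 2·(k + 1 + 1{structure parameter estimated})`, the
  `+1` counting σ². AIC (not AICc) is the default ranking criterion; an
  AICc variant was considered and rejected as the default to keep the
  ranking criterion the plain AIC, but the comparison report exposes all
  ingredients (logLik, k, n) so either can be recomputed.
* ML is the default everywhere so AIC comparisons across fixed-effect sets
  are valid; REML is available (`method="REML"`) because reference GLS
  implementations in the R ecosystem default to it and standard errors can
  differ slightly. Likelihood-ratio tests refuse non-ML fits.

### Profile search for λ and α

λ is profiled over a 41-point grid on `[0, 1]`, then refined with bounded
scalar minimization between the neighbors of the grid optimum (tolerance
1e−8). α is profiled on a 41-point log-spaced grid over
`[1e−4/T, 1e2/T]` with `T` the tree depth, refined in log space. The
grid-then-refine scheme is robust to the multimodal profiles that small
samples (n ≈ 16) produce. A fitted parameter within 1e−6 of a search bound
sets a boundary flag on the fit.

## Model selection

`enumerate_models` generates every subset of the optional predictors
(mandatory predictors always included, total size capped), in
deterministic lexicographic order. `compare_models` fits each spec under
each requested structure (per-model structure competition is the default;
fixing one structure globally is a matter of passing a single-element
structure tuple), skips infeasible fits (complete cases `< k+2`) with a
logged reason, and ranks by AIC with ties broken by fewer predictors then
lexicographic predictor list. The comparison report adds ΔAIC and Akaike
weights `exp(−Δ/2)/Σexp(−Δ/2)`.

## Jackknife

`leave_one_out` removes each species from both the trait table and the
tree (edge fusion preserves all surviving path lengths), refits the
selected model, and reports per predictor the removals that flip
significance at `α = 0.05` (losses and gains separately) and those that
flip the coefficient sign. The structure parameter is re-estimated in
every replicate by default — the procedure re-fits the selected *model
specification*, not the frozen covariance — with `freeze_parameter=True`
available for sensitivity analysis. Re-selection of the best model per
replicate is deliberately not performed: the procedure assesses the
selected model's stability, not the selection's.

## Data handling

* Species labels: whitespace and underscores are interchangeable
  (`Pan troglodytes` ≡ `Pan_troglodytes`); matching is case-sensitive
  after normalization.
* Brain volumes and body mass are log10-transformed; daily traveled
  distance (km) and population density (individuals/km²) enter on their
  raw scales, which is what gives the characteristic coefficient
  magnitudes (~0.05/km, ~0.007 per individual/km²).
* Multiple specimens per species are averaged on the raw volume scale
  *before* the log transform (log-of-mean, not mean-of-logs). This is a
  documented convention, chosen because species-average volumes are the
  quantity being modeled.
* The dietary quality index is `DQI = 1s + 2r + 3.5a` over the diet
  percentages of plant structural parts, plant reproductive parts and
  animal prey; ~100 indicates folivory, ~200 a diversified diet.
* Categorical predictors are treatment-coded against a configured
  reference level; binary traits become single 0/1 columns.
* Rows with missing values are dropped per fitted model (complete-case per
  model) with a logged count; the table is treated as given, with no
  imputation.
* Collinearity screening reports pairwise Pearson correlations and flags
  `|r| > 0.7` by default.

## Synthetic data

The generator produces exactly the process the model assumes, so every
pipeline stage is testable without external data.

* **Trees**: pure-birth (Yule), forward-simulated with exponential waiting
  times, run one extra interval past the n-th birth so terminal branches
  are positive, then rescaled to unit root-to-tip depth (ultrametric).
* **Predictors**: Brownian-on-tree (MVN with covariance `rate·V`), iid
  normal, iid log-normal, or categorical; draws use a Cholesky factor with
  the same jitter fallback as the fitter.
* **Response**: intercept + linear predictor + MVN noise under a chosen
  structure and σ².
* **Default scenario** (the study-scale conditions): 16 tips; effects
  0.47 (log10 body mass, BM on the tree, root state 3.8, rate 0.36),
  0.05 (daily traveled distance, normal mean 3 km sd 1.5) and 0.007
  (population density, log-normal median ≈ 20 individuals/km²); intercept
  4.26; Brownian errors with σ² = 0.02 (residual sd ≈ 0.14 on the log10
  volume scale). The effect magnitudes and intercept are the published
  whole-brain coefficients; predictor scales and σ² are chosen once to
  give realistic primate values and coefficient t-statistics of the
  published order, and are not tuned thereafter.
* **Reproducibility**: one `numpy` Generator stream per replicate, seeded
  counter-style as `default_rng([seed, rep])`, so any replicate can be
  regenerated in isolation.

What the generator does *not* emulate: measurement error in volumes,
intra-specific variability, missing-data patterns, correlated predictors,
non-Gaussian trait evolution, or uncertainty in the tree itself. Passing
calibration tests therefore demonstrate correctness of the estimator under
its own assumptions, not robustness to their violation in real data.

## Calibration checks and problem sizes

The simulate-and-refit experiments run at n = 100 tips (200 replicates for
bias/coverage, 500 for likelihood-ratio calibration, 100 for AIC selection
consistency), a size where GLS finite-sample behavior and the asymptotic
chi-squared reference for the LRT are both well behaved; the default
16-species scenario is used for structural and contract checks. A caveat
worth stating: the chi-squared LRT reference is asymptotic and measurably
anti-conservative at small n (at n = 50 the exact rejection rate of the
nominal 5% test is ≈ 5.9%, and it is larger still at n = 16), so
small-sample LRT p-values should be read as approximate. The selection
pool in the consistency check includes one pure-noise candidate; AIC's
known ~16% chance of admitting one irrelevant predictor bounds the
achievable exact-recovery rate near 84%.

## Known limitations

* No measurement-error ("SE in variables") models, phylogenetic mixed
  models with intra-specific replicates, or multivariate-response PGLS.
* Single fixed tree: no averaging over a posterior tree set.
* OU is a correlation structure only (no stationary-variance form).
* λ's search interval is `[0, 1]` even on non-ultrametric trees where a
  slightly larger upper bound can remain positive definite.
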