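# Methods

## Model and estimators

The estimation unit is the cell: a district × age-group × sex cross.
The hierarchy has three levels — regions `r = 1..R` (fixed effects vary
systematically), districts `d = 1..D_r` (random effects vary), cells
`c = 1..C` (residual variation).  Per region the member data follow the
linear mixed model

    ỹ_r = X̃_r β_r + Z_r b_r + e_r,
    b_rd ~ N(0, Ψ),  e_r ~ N(0, σ²_r I),  Cov(b, e) = 0,

with `Z_r = diag(Z_r1, …, Z_rD_r)` block-diagonal over districts.  The
response is the diseased member *count* per cell; cell size enters the
fixed effects.  Counts rather than proportions keep the model linear in
the auxiliary diagnosis counts, whose relation to the outcome is the
quantity the benchmark extrapolation transfers; the homoscedastic
within-region error is then an approximation, and the estimated σ²_r
absorbs the count-level (binomial-type) noise on top of any structural
cell error.  Fixed-effect estimates β̂ are unbiased under this
misspecified covariance; only efficiency is lost.

Because `V_r = Z_r Ψ_r Z_r' + σ²_r I` is block-diagonal over districts,
every REML evaluation reduces to batched algebra on blocks of at most
`C` rows.  The variance ratio `Γ = Ψ/σ²` is profiled: given Γ, the GLS
fixed effects, σ̂² and the restricted likelihood are closed-form.  Γ is
parameterized by the log-Cholesky factor (positive semidefinite without
constraints) and optimized by a bracketed high-precision scalar search
for Q = 1 (the default district random intercept) or L-BFGS-B from
three deterministic starts for Q ≥ 2; the boundary Ψ = 0 is always
evaluated and adopted when at least as good, so degenerate truths yield
exact zeros.  The reported restricted log-likelihood includes the
`½ log|X'X|` normalization, making it invariant under full-rank
reparameterizations of the fixed effects.

National predictions are `ŷ_rd^c = x_rd^c'β̂_r + z_rd^c'b̂_rd`, with the
district random effect retained.  Districts without member data fall
back to the fixed-effect part (`b̂ = 0`) and are flagged.  Raw
predictions are clamped to `[0, N_rd^c]` with a logged count of clamped
cells — the linear-Gaussian model is unconstrained, so range
enforcement is a reporting decision, kept out of the fitting itself.
Aggregates at any level (district, region, age group, sex, national)
are exact sums of cell predictions over sums of national cell sizes, so
any two nested aggregation paths agree to machine precision.

Model comparison offers an ANOVA branch (likelihood-ratio statistic on
ML log-likelihoods evaluated at the REML variance estimates, chi-square
reference on the fixed-effect difference; restricted likelihoods are
not comparable across fixed-effect structures) and a conditional
information criterion `−2·ℓ_cond + log(n)·edf` with the BIC-strength
penalty.  The effective degrees of freedom are the trace of the hat
matrix mapping the response to `Xβ̂ + Zb̂`; with the response-free
limit Ψ → 0 this trace reduces to P.  The hat-trace definition is one
of several circulating for conditional criteria; it is adopted here
because it is exact, cheap in the blocked representation, and
interpolates between P and P + Q·D as shrinkage relaxes.

## Variable selection

Per region, candidates are ranked by the absolute Pearson correlation
between the member prevalence proportion and the candidate's member
per-capita rate over non-empty cells (rates, not raw counts, to remove
the trivial cell-size channel).  A candidate is elected in a region when
it enters that region's top-k; the final set is the `p_sel` most
frequently elected candidates, ties broken by mean absolute correlation
and then label.  Defaults `top_k = p_sel = 10`; main and secondary
diagnoses of the same ICD-3 code compete as separate candidates.
Zero-variance candidates (relative tolerance 1e-12) get correlation 0
with a logged warning.

## Synthetic study conditions

The generator emulates the structure of German claims research: a
national population on a dense cell grid, a fund member subset, and
cell-level inpatient diagnosis counts for both populations.  Reference
conditions (`default_scenario()`):

- **Hierarchy**: 2 model regions × 10 districts × 8 cells (4 age
  groups × 2 sexes); cell sizes lognormal around 20,000 with an age
  profile — the order of magnitude of real district/age/sex cells
  (a country of ~80M over ~3,200 cells).
- **Morbidity**: a latent score `s = age + sex + district + cell noise`
  (district sd 0.15, cell sd 0.35) drives per-capita auxiliary rates
  `rate_j = r_j · exp(w_j s + τ ν_jc)`.  Three planted comorbidity
  columns (base rates 0.10/0.09/0.08 per capita, shared loading
  w = 0.7, idiosyncratic τ = 0.7) carry true coefficients
  β = 0.25 each; 27 further ICD-3-style candidates are
  morbidity-unrelated noise.  The resulting national prevalence is
  8–10%, the range of common chronic diseases such as type-2 diabetes.
- **Outcome**: expected count `μ = x'β + b_d + e` on the *realized*
  national auxiliary counts, with district intercept variance
  ψ = 900 (sd 30 counts) and cell error σ² = 625 (sd 25); the realized
  count is binomial with matching mean (a degenerate-noise switch
  replaces it by deterministic rounding for exactness tests).
- **Membership**: per-person cell-level propensities on the logit
  scale.  Healthy citizens join at `expit(−0.62 + 0.12·age − 0.05·male)`
  (≈ one third of the population); diseased citizens and
  hospital-treated cases carry a +0.7 morbidity offset.  Member
  auxiliary counts are binomial thinnings of the national counts at the
  morbid-class propensity — the fund's hospital records are a subset of
  the national census.  This plants a ~40% relative member-vs-national
  prevalence gap that demographic rescaling cannot remove, while the
  *same* thinning rate for outcome and auxiliary counts makes the
  member→national relation transfer: the identifying equality of
  conditional expectations holds by construction.
- **Violation switch**: `informative_beyond_aux=True` adds a +0.3 logit
  offset for diseased citizens *beyond* hospital-treated ones —
  membership information about the disease the auxiliary data cannot
  carry.  Under it the benchmarked estimator is biased by design
  (≈ +15% relative under the defaults), which the validation harness
  reports rather than hides.
- **Proxy endpoint**: optionally a hospital-observed column generated as
  a linear combination of planted columns — exactly (for the
  noiseless-recovery check) or Poisson around that mean with binomial
  member thinning; a logit `distortion` plants a member/national
  relation the extrapolation cannot recover.

All randomness flows from one root seed through stage-labelled child
generators (CRC-32 keyed `SeedSequence`) over the canonical cell order:
identical (scenario, seed) pairs reproduce bit-for-bit.

What the generator does *not* emulate: real German marginals, person
-level records, spatially correlated district effects, and reporting
artefacts of claims data (miscoding, incomplete enrolment spells).
Passing tests therefore show that the methodology recovers truth under
its stated assumptions at realistic scale — not that any particular
real-world dataset satisfies those assumptions.

Because member auxiliary counts are binomial thinnings, they are noisy
measurements of the signal that generated the outcome; this induces a
small attenuation-type transfer error that shrinks with cell size and
with the between-cell variance of the auxiliary rates.  At the
reference conditions it is below ~0.1% relative on the national
estimate — an order of magnitude under the Monte-Carlo resolution of
the studies below.

## Uncertainty

The semiparametric bootstrap follows the residual-resampling scheme for
multilevel models: per region, predicted district effects and
conditional residuals are centered and reflated so their empirical
second moments equal (Ψ̂, σ̂²) exactly, then resampled independently
with replacement; pseudo-responses `y* = X̃β̂ + Zb* + e*` are refitted
and re-extrapolated, and percentile intervals are read from the
replicate distribution (no normality assumption).  Resampling is done
within region, matching the region-specific σ²_r.  Replicates whose
refit fails to converge are dropped and logged; more than 10% drops
flag the summary invalid.  Default B = 1000; the studies below use
B = 200.

The intervals quantify the uncertainty the model describes —
random-effect and residual variation propagated through refitting,
conditional on the observed auxiliary data.  Sampling noise *of* the
auxiliary counts is not propagated; the coverage study therefore uses
conditions where the model's stochastic components dominate
(ψ = σ² = 2500), under which 95% intervals cover the realized national
prevalence in ≈ 93–96% of runs.  Under auxiliary-noise-dominated
conditions percentile intervals are anti-conservative — a known
limitation shared with any conditional resampling scheme.

## Validation designs and problem sizes

- *Monte-Carlo validation*: populations are generated under a scenario
  grid, the full pipeline runs per replicate, and bias/RMSE of the
  adjusted estimator and the naive baseline are scored against the
  generated truth.  Estimation never reads the truth column (enforced
  by a test); scoring does.  Reference studies use 200 replicates; at
  that size the Monte-Carlo standard error of the national relative
  bias is ≈ 0.1%.
- *Parameter recovery*: region models are fitted on the national
  outcome with known (β, Ψ, σ²) at D_r = 50 and D_r = 10 (200
  replicates each); mean estimates match truth within Monte-Carlo
  error and RMSE shrinks with district count.
- *Bootstrap coverage*: 200 Monte-Carlo runs × B = 200.
- *Proxy cross-validation*: 200 replicates of the noisy-proxy study;
  the exact-proxy check is a single deterministic recovery to < 1e-6
  relative error.

These sizes keep each study in the seconds-to-minutes range on a single
core while leaving Monte-Carlo error well below the effects being
demonstrated (planted gap ≈ 40%, naive bias ≈ 40% relative, adjusted
bias ≲ 0.2% relative).

## Numerical choices

- REML scalar search: bracketed bounded minimization on `t = log γ`
  over [−16, 12] after a 10-point grid scan, `xatol = 1e-10`;
  L-BFGS-B (`ftol = 1e-13`) with three deterministic starts for Q ≥ 2.
- Exact-fit guard: a vanishing profiled residual sum of squares is
  floored at 1e-300 inside the log; σ̂² = 0 fits report infinite
  log-likelihoods and zero-width bootstrap intervals.
- Rank checking by pivoted QR with tolerance
  `max|R_ii| · max(n, P) · eps`, naming the collinear columns.
- Ties in the election stage break deterministically (mean |corr|,
  then label), so selection is auditable and reproducible.
- Aggregation uses exact summation; additivity across nested paths is
  asserted to 1e-12.

## Known limitations

- Gaussian count-scale model: no Poisson/logistic variant; regions with
  a substantial share of member-free cells would need zero-inflation
  handling that is out of scope.
- No spatial correlation between district effects; no crossed random
  effects.
- The bootstrap is conditional on the auxiliary data (see above).
- The generator's truth uses a district random intercept (Q = 1); the
  fitting machinery supports arbitrary Q, exercised in unit tests via
  synthetic designs rather than through the generator.
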