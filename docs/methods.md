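# Methods

## Model

`nestedvar` fits the three-level nested random-intercept Gaussian model

    y_ijk = x_ijk' β + v_k + u_jk + e_ijk

for baby *i* of mother *j* born in country *k*, with

    v_k  ~ N(0, σ²_mcb),   u_jk ~ N(0, σ²_m),   e_ijk ~ N(0, σ²_b),

mothers strictly nested in countries (a mother appearing under two
countries is rejected at data preparation).  Two-level reductions (drop the
mother level, or model mothers-in-countries directly) use the same code
path.  Assumptions: Gaussian homoscedastic components at every level,
random intercepts only (no random slopes, no cross-classification), and
covariates entering linearly through dummy coding.

The model sequence mirrors the classical build-up: Model 1 is the empty
model (intercept plus all random levels); Models 2–5 add cumulative
fixed-effect blocks (maternal stature; maternal age; all individual
covariates including sex, centred gestational age, household income,
marital status, smoking, hypertension, diabetes; country income class).

## Estimation

**Start values** come from Henderson-type method-of-moments estimators:
nested-ANOVA quadratic forms of OLS residuals with exact unbalanced-design
coefficients, reducing to the classical balanced nested ANOVA on balanced
data.  Negative moment estimates are floored at 1e-8 × the outcome
variance (floored, not zeroed, so the sampler can move off the boundary).
Fixed effects at this stage are feasible GLS at the moment components.

**The production fit** is a blocked Gibbs sampler with closed-form full
conditionals: the fixed-effect vector jointly normal given the effects and
variances; each country and mother effect normal given the rest (vectorised
over clusters); each variance inverse-gamma given its effects.  Priors are
flat (improper) on fixed effects and inverse-gamma(0.001, 0.001) on each
variance — the conventional diffuse choice for this model family; both are
exposed in `MCMCSettings`.  Defaults are 500 burn-in and 5,000 monitoring
iterations, thinning 1.

Because one country typically holds ~80% of the cohort, the intercept and
the country effects are nearly confounded, which stalls plain Gibbs
updates.  After each effect block we therefore apply a generalized-Gibbs
translation move (a "sweep"): draw δ ~ N(mean of effects, σ²_level/K),
subtract δ from the effects and add it to the intercept.  This is an exact
MCMC move (the translation-group move sampled from its conditional
density), not a deterministic recentering, so the stationary distribution
is untouched while intercept/effect drift is eliminated.

Point estimates are posterior means, uncertainty is the posterior SD, and
intervals are equal-tailed 2.5/97.5 percentiles.  Per-iteration cost is
linear in the number of babies; all cluster updates use `bincount`
reductions and no n×n matrix is ever formed.  A fit of the full synthetic
study structure (~28,500 babies, 5,500 iterations) takes under ten seconds
on one CPU.

**Marginal deviance.**  −2 log L with the random effects integrated out is
computed level-wise: the mother blocks are inverted in closed form, and the
country level enters through a diagonal capacitance matrix (mothers nest in
countries), giving O(n) evaluation of both the quadratic form and the log
determinant.  The DIC is `D̄ + pD` with `pD = D̄ − D(posterior means)`,
evaluated on at most 1,000 equally spaced retained draws.  Note this is the
*marginal* deviance; software that conditions on the random effects reports
a different absolute deviance scale, so DIC values are comparable within
this package only.

**Test oracle.**  `oracle_direct` assembles the dense covariance
σ²_mcb·ZcZc' + σ²_m·ZmZm' + σ²_b·I explicitly (≤500 rows) and maximises
the exact likelihood by Nelder–Mead on log variances with the fixed effects
profiled out by GLS.  It exists for cross-checking the sampler and the
level-wise deviance; it is never the production path.

## Partition statistics

From a fit's variance components:

- VPC per level: 100·σ²_level / (σ²_mcb + σ²_m + σ²_b);
- ICC at the country level equals the country VPC; at the mother level it
  is 100·(σ²_mcb + σ²_m)/total — the correlation between two babies of the
  same mother;
- PCV per level: 100·(σ²_model − σ²_ref)/σ²_ref against the empty model,
  with a total over summed components.

Computation is at full precision; display rounds to one decimal, half away
from zero, which reproduces the usual printed tables.  Reconstructing a
published five-model table from rounded components can leave isolated cells
off by 0.1 (rounding of already-rounded inputs); the test suite allows at
most two such cells.

## Shrunken country effects

The league table ranks countries by the posterior mean of v_k — the
empirical-Bayes deviation of a country's mean from the grand mean across
countries (not from the dominant country).  Intervals are equal-tailed
posterior percentiles of the v_k chain; ranks break ties by country id so
output is deterministic.  In a balanced two-level setting the posterior
mean reduces to the classical shrinkage factor σ²_c/(σ²_c + σ²_b/n) applied
to the raw deviation, which the tests verify against the chain.

## Synthetic generator

The generator emulates the statistical structure of a national birth
register dominated by one country of origin:

- ~109 countries; the dominant one takes 80% of mothers; remaining shares
  follow a symmetric Dirichlet (concentration 0.5 → heavily skewed sizes);
- 1–3 babies per mother with probabilities (0.62, 0.34, 0.04), mean ≈1.42;
- default variance components (7,699, 111,583, 119,871) g² at the
  country/mother/baby levels;
- covariate category frequencies from the emulated population's printed
  proportions (vectors renormalised where printed percentages do not sum
  to exactly 100); gestational age Normal(39.66, 1.27) rounded to integer
  weeks and truncated to [37, 42] by resampling;
- default fixed effects are the fully adjusted model's coefficients, with
  gestational age contributing through its centred value;
- country income class drawn per country from the printed class shares.

Covariates are sampled independently of each other and of the latent
effects: the generator exists to test *estimation*, not confounding, and
the emulated study does not report the joint covariate distribution.  A
`covariate_sampler` hook accepts a user-supplied joint sampler for richer
scenarios.  Consequently, passing tests demonstrate correct recovery of
variance components and coefficients under the assumed model; they say
nothing about robustness to covariate–effect correlation, informative
cluster sizes, or non-Gaussian outcomes, none of which the generator
produces.

**Empty-model scenarios.**  The printed empty-model components of the
emulated study already contain covariate-driven variation (sex and
gestational age inflate the baby level, stature the mother level, income
class the country level).  Variance-recovery scenarios therefore use
`empty_model_config()` — covariate effects switched off, intercept 3,490 g —
so the configured level variances are exactly the marginal ones the empty
model should recover.  Coefficient-recovery tests use the full
`default_config()` and fit the adjusted model instead.

**Maternal stature** is generated from a two-level normal model with a
configurable between-country share (default ICC 24%, total variance
40 cm², mean 165 cm).

## Scenario and fixture design

- **Planted-signal league recovery**: 9 of 30 countries are shifted
  −250 g; the dominant country holds 50% of 30,000 mothers and the rest are
  near-equal in size so every planted country carries ~700+ babies.  The
  residual between-country SD is set to 30 g so the shift is more than
  eight residual SDs: with the full default between-country SD (88 g) the
  nine lowest *true* effects would frequently not be the planted nine
  (−250 g ≈ 2.8 SD against 21 null draws), i.e. exact rank recovery would
  be ill-posed at truth level, not merely underpowered.
- **Sampler-vs-oracle fixture**: 25 countries × 4 mothers × 2 babies
  (200 rows) at variances (4,000, 1,500, 800).  The design keeps the
  country variance well above its contamination (σ²_m/4 + σ²_b/8) and gives
  75 within-country mother contrasts, so the posterior-mean-vs-ML gap stays
  far inside the 25% comparison band; sparser designs (2 mothers per
  country) create a σ²_mcb/σ²_m likelihood ridge on which the two
  estimators legitimately diverge.
- **Replicate medians**: end-to-end recovery of the country-level share is
  summarised as the median over 10 replicate seeds; a single realisation of
  100 country effects has ~14% sampling noise in its variance before any
  estimation error.

## Problem sizes and runtime

The test suite runs everything at reduced scale: covariate-model fits on
~2,500-mother cohorts, recovery replicates at 50 countries × 8,000 mothers,
and the full study structure (100 countries × 20,000 mothers ≈ 28,500
babies) only in the end-to-end checks.  The acceptance script runs ten
replicates of the full structure plus ten stature fits in about two
minutes on one CPU.

## Numerical choices

- Gestational age is grand-mean centred by default (`ModelSpec`
  configurable): the adjusted-model intercept is only interpretable as a
  mean birthweight at average gestation if the continuous covariate is
  centred.
- "Missing" is an ordinary category with its own dummy and coefficient;
  rows are never dropped for a missing covariate value.
- Income tertiles cut at the 1/3 and 2/3 quantiles of non-missing values
  (linear interpolation); values exactly at a cut point go to the lower
  category, so an all-constant column is all "lowest".
- Box-plot summaries use the Tukey convention: quartiles by linear
  interpolation, whiskers at the most extreme observations within
  1.5 × IQR of the quartiles.
- League-table ties break by country id; filter rules run in a fixed
  documented order with the per-country minimum applied once, after all
  row-level rules (not iterated).
- Chains are reproducible bit-for-bit given `MCMCSettings.seed`; the
  generator is reproducible given its seed.

## Limitations

- No random slopes, cross-classified factors, or non-Gaussian outcomes.
- The moment start uses OLS residuals, which slightly biases its components
  under strong covariate imbalance; this only affects the start, not the
  posterior.
- DIC is on the marginal-deviance scale (see above) and is not comparable
  with conditional-deviance implementations.
- The generator's covariate independence means adjusted-model PCVs on
  synthetic data are small by construction; reproducing a published PCV
  pattern requires the real register's covariate–country correlation, which
  is deliberately out of scope.
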