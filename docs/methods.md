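# Methods

This note documents the statistical model, the numerical scheme, the
defaults and the design choices behind `metareg`, and what the synthetic
data do and do not establish about behaviour on real evidence bases.

## Data model and coding rules

The unit of analysis is a comparison observation: a mean difference (MD) in
change-from-baseline zBMI between an intervention arm and a reference arm of
the same trial at one follow-up time, with a standard error taken as known
(cluster adjustment is assumed to have happened upstream). Binary
indicators code characteristics at three levels; control arms are by
definition the absence of any intervention and carry no indicators.

Deterministic coding rules, all with declared conventions where a convention
is needed:

- **Follow-up categories**: short = 12 weeks to <9 months, medium = 9 to
  <15 months, long = ≥15 months. Months are converted at 1 month =
  365.25/84 ≈ 4.348 weeks (a twelfth of a Julian year in 7-day weeks); the
  15-month boundary is inclusive into `long`. Follow-ups under 12 weeks are
  outside the domain and rejected.
- **Time-point selection**: where a comparison is reported at several times
  within one category, the time closest to the category target is kept —
  the interval midpoint for short and medium, 24 months for the open-ended
  long category. Exact ties go to the earlier time (an arbitrary but fixed
  convention; ties are measure-zero in real data).
- **Duration dichotomisation**: long = duration ≥ median across coded
  interventions (default 30.33 weeks), boundary inclusive.
- Missing indicator values are rejected, not imputed: the schema expects a
  fully coded dataset.

CSV is the interchange format, one row per observation, with `ref_*`
columns carrying the reference arm's indicators for active-referenced
comparisons. Reading uses round-trip float parsing so write→read is the
identity.

## Outcome mapping

Three mappers convert reported summaries to mean zBMI:

- **BMI → zBMI** (sampling, default 10,000 draws): BMI lognormal with
  moments matched to the reported mean/SD (σ²_log = ln(1 + SD²/mean²),
  μ_log = ln mean − σ²_log/2), age normal truncated to the growth-reference
  range (truncated mass is noted in the result), sex Bernoulli(prop_male);
  each individual passes through the LMS z-score
  z = ((BMI/M)^L − 1)/(L·S), with the log-form limit used for |L| < 1e−7.
  The Monte-Carlo standard error of the mean is reported.
- **Percentile → zBMI** (analytic, exact): if zBMI ~ N(μ, σ²), the
  percentile 100·Φ(Z) has mean 100·Φ(a) with a = μ/√(1+σ²) and second
  moment 10⁴·Φ₂(a, a; ρ) with ρ = σ²/(1+σ²), the equal-threshold bivariate
  normal orthant probability, evaluated via Owen's T to machine precision.
  Inversion: a comes directly from the reported mean; ρ from the reported
  SD by a monotone 1-D Brent solve (tolerance well below the stated 1e−8);
  no solution with σ ≤ 10 is an error. SD → 0 degenerates to
  μ = Φ⁻¹(mean/100).
- **Prevalence → zBMI**: proportions above z-score thresholds (defaults
  1.036 and 1.645, the 85th/95th reference percentiles, overridable) give
  linear equations in (μ, σ) in probit space; with a single category σ is
  fixed at the reference value 1 and the result flagged. Boundary
  proportions (0 or 1) and threshold-inconsistent orderings are errors.

The LMS reference is pluggable (CSV: sex, age_years, L, M, S; linear
interpolation in age). The bundled `synthetic_reference()` is a smooth
synthetic table for self-contained tests and examples — it is **not** a
population growth chart, and production analyses should load CDC/WHO or
national tables. Mapping applies at the arm-summary level; mapped arm means
are differenced downstream exactly like directly reported zBMI.

## Screening

Pairwise phi (= Pearson on 0/1 columns) correlations over active arms;
pairs with |φ| ≥ 0.5 are flagged (inclusive boundary), as are pairs
agreeing on more than 80% of arms (strict boundary) — both boundaries read
literally from their definitions. Constant columns are reported, not
correlated. Merging is the logical OR under a combined label; which pairs
to drop/merge is configuration (the screening *procedure* is code, the
choices are data), and protected indicators can never be dropped. The two
behaviour dummies are intentionally mutually exclusive and will flag as
negatively correlated; they are retained as the two-dummy coding of a
three-level factor.

## The meta-regression

### Mean structure

Design rows are built from an arm-level covariate vector
φ(arm) = [1, x, w, v, products]; a control-referenced observation
contributes φ(a), an active-referenced one φ(a) − φ(b), which cancels the
intercept, trial- and time-level terms and any product not involving an
intervention-level indicator — exactly the statement that such comparisons
do not inform those parameters (their design entries are identically zero,
so this holds exactly, not just in expectation). Interaction products are
formed per arm before differencing. Centring subtracts each covariate's
mean over observation rows from control-referenced rows (active-referenced
rows are differences and are invariant); the stored means de-centre the
intercept as α_unc = α_c − Σ coef·mean.

### Covariance structure

Per trial, the residual block R has se² on the diagonal,
ρ_time·se_i·se_j between the same comparison at different times (default
0.8; 0.5 and 0.95 as sensitivity settings) and ρ_arm·se_i·se_j between
different comparisons sharing a reference arm (default 0.5, the
equal-variance common-control heuristic; configurable). Blocks failing a
positive-definiteness check get a ridge of 1e−10·max(diag) with a logged
warning; still-degenerate blocks are a hard error.

Random effects u are indexed by (active arm, follow-up category) with
Var = τ² and Cov = τ²/2 between any two distinct effects in the same trial,
i.e. Σ_u = (τ²/2)(I + J). This is the exchangeable multi-arm assumption
extended verbatim to follow-up times. An observation loads +1 on its arm's
effect and −1 on an active reference's effect, giving marginal covariance
R + τ²C with C = Z(I+J)Zᵀ/2; an active-vs-active contrast keeps variance τ²
under this structure.

### Priors and sampling

Coefficients get Normal(0, 10²) — effectively flat for zBMI effects, which
are ≪ 1 in magnitude — and τ gets Uniform(0, 2); both are configurable.

The sampler is a blocked Gibbs scheme built on a one-off simultaneous
diagonalisation: per trial, R = LLᵀ and C̃ = L⁻¹CL⁻ᵀ = QΛQᵀ, after which the
whitened model has independent rows with variances 1 + τ²λ_k. Each
iteration draws the full coefficient vector exactly from its conjugate
multivariate-normal conditional (a weighted ridge regression with weights
1/(1+τ²λ)) and updates τ by shrinkage slice sampling of its bounded
univariate conditional. There are no accept/reject tuning parameters. Chain
c uses `default_rng([seed, c])`, so fits are deterministic given the seed.
Fixed-effects mode pins τ = 0 in the same machinery.

Defaults: 2 chains, 2,000 post-warmup draws after 1,000 warmup iterations.
Convergence is reported per parameter (split-R̂ and effective sample size
via arviz); R̂ ≥ 1.05 flags the fit as unconverged (logged and exposed as
`converged=False`), never silently passed. P(<0)/P(>0) are the fractions of
draws strictly below/above zero; draws exactly at zero count to neither
side.

### SSVS

Candidate interaction coefficients get the two-component mixture prior
spike = Normal(0, 0.01²), slab = Normal(0, 1²), prior inclusion probability
0.5, all configurable; the latent Bernoulli indicators have conjugate
updates inside the same Gibbs sweep, and the inclusion frequency is the
posterior mean of the indicator. Selection threshold: frequency strictly
above 0.5. The stepwise procedure runs (i) no interactions, (ii) age ×
every other indicator (k−1 candidates), (iii) each behaviour dummy × every
other indicator except its mutually exclusive partner (2(k−2) candidates),
stages independent, final set = union of selections from (ii) and (iii)
de-duplicated by canonical label. The full 276-pair joint search is not run
by default (it is statistically and computationally ill-posed at this data
size) but nothing prevents passing an arbitrary candidate list to
`run_ssvs`. If spike SD ≥ slab SD the mixture is unidentified and
frequencies collapse to the prior; this is warned about and covered by a
test.

## Combination profiling

Plausibility rules: the two dummy pairs (medium, long) and (diet_and_pa,
pa_only) are mutually exclusive, and at least one mechanism-of-action
indicator (participation, education, social_env, physical_env) must be 1.
With 24 indicators that leaves 2¹⁶·3·3·15 = 8,847,360 rows; counts come
from the closed-form product over rule blocks and enumeration is a
deterministic mixed-radix decoding, chunked so the grid never has to be
materialised. Predictions use the posterior-mean coefficients on the
de-centred scale (the posterior mean of the linear predictor equals the
linear predictor at posterior means); no posterior uncertainty is
propagated over the grid — ranking is by point prediction only. Extremes
report all tied argmin/argmax rows; the 1% tails contain ceil(0.01·N) rows
with the boundary value inclusive. Subgroup searches pin trial- or
time-level indicators and re-profile; the risk-of-bias indicator is
enumerated like any other by default but can be pinned (e.g. rob_high=0)
since a "best" combination conditioned on bias is interpretively odd.

## Synthetic-data generator

The generator emulates the study conditions: 204 trials; 25% of trials
carry a second intervention arm and 2% consist of two active arms with no
control (an active-vs-active comparison), giving ~255 active arms and ~250
comparisons; 18% of comparisons are observed at two follow-up categories
(~295 observations); category weights (0.27, 0.39, 0.34) over
(short, medium, long); indicator marginals at the observed coding-table
percentages, with the behaviour pair drawn as a three-level categorical and
the mechanism block resampled until at least one indicator is 1; true
coefficients defaulting to the primary-analysis posterior means (α = −0.037
on the uncentred scale, pa_only = −0.227, τ = 0.080, and the other reported
non-null effects; near-zero estimates set to 0); SEs lognormal with median
0.05 zBMI units and σ_log = 0.5, typical of the field. Observations are
y = Xθ + Zu + ε with u and ε drawn from exactly the model's covariance
structures; the truth record stores every latent quantity, and generation
is deterministic given the seed.

What the generator does **not** emulate: dependence between indicators (they
are independent at their marginals; screening tests plant correlated pairs
explicitly), informative selection of follow-up times, non-normal residuals,
SE heteroscedasticity linked to arm size, or coding error. Passing
parameter-recovery and calibration tests therefore shows the inference is
correct *under the model's own assumptions* at realistic scale and effect
sizes — it does not validate those assumptions against real trial data.

## Verification strategy and problem sizes

- The percentile mapper is checked against 10⁶-draw Monte-Carlo simulation
  on a 9-point (μ, σ) grid within 3 MC standard errors, and inversion of
  the MC moments recovers the truth within perturbation-propagated MC
  tolerances.
- The blockwise marginal likelihood is checked to 1e−8 against explicit
  Gauss–Hermite integration (30 nodes/dimension) of the random effects on
  2-arm × 2-time toy trials, control- and active-referenced. The toy SEs
  are chosen comparable to τ so the prior-scaled quadrature grid covers the
  integrand well.
- Parameter recovery runs 20 study-scale replicates at 2 chains × 2,000
  draws and requires 95% CI coverage of (α, the 18 β, τ) within three
  standard errors of nominal, where the SE is the larger of the
  independent-binomial value and a seed-clustered estimate (coverage
  indicators within a replicate are correlated, so the clustered SE is the
  honest one).
- Fixed-effects ≡ random-effects-at-τ=0 and centring invariance are checked
  within Monte-Carlo error (4× the ESS-based MC standard errors, different
  seeds on purpose so agreement is statistical, not mechanical).
- SSVS calibration: on null data the median inclusion frequency across age
  candidates stays below 0.5; a planted age×electronic interaction of −0.3
  (≈6× the median observation SE) must be selected in ≥80% of 10
  replicates.
- Enumeration is checked exactly against brute-force filtering on toy
  systems and the closed-form 8,847,360 count.

These sizes keep the full test suite under a couple of minutes on one CPU
while leaving the checks statistically meaningful; they are the package's
chosen verification scale, and all of them rerun from scratch in
`scripts/acceptance.py`.

## Known limitations

- The within-trial covariance for comparisons sharing a reference arm uses
  a single configurable ρ_arm rather than deriving the induced correlation
  from arm-level variance components; 0.5 is exact only for equal-variance
  common-control contrasts.
- The percentile and prevalence mappers assume normal zBMI within arm; the
  BMI mapper assumes lognormal BMI and normal age. Skewed cohorts violate
  these.
- Combination profiling ranks by posterior-mean prediction only; two
  combinations whose predictions differ by less than posterior uncertainty
  are not distinguishable, and the profile tables should be read
  accordingly.
- The sampler exploits the linear-Gaussian structure; models outside it
  (e.g. non-normal likelihoods, hierarchical priors on coefficients) would
  need a different kernel.
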