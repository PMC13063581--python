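# Methods

## Analysis population

The selection flow keeps cis-male survey completers (male gender identity
and male sex assigned at birth) with a stated PrEP status of *current* or
*never*; former users, self-reported repeat participants across waves and
non-users without a confirmed negative HIV status are removed. The
remaining records must satisfy the PrEP-indication predicate:

* sexualized drug use in the last six months, **or**
* ≥ 1 diagnosis of syphilis, gonorrhea, chlamydia or hepatitis C in the
  last twelve months, **or**
* ≥ 2 anal/vaginal sex partners in the last six months together with
  condom use in 0–50% of contacts — the condom clause applies to non-users
  only, since infrequent condom use is the norm among PrEP users.

A missing answer never satisfies a clause: eligibility must be
demonstrated, not assumed. (The alternative — treating missing as
potentially eligible — would admit records whose indication cannot be
established.) Current users failing the predicate are simply removed by
the indication filter rather than specially flagged. All filters are
record-level predicates, so the final cohort is order-invariant; only the
ledger's intermediate counts depend on the fixed flow order. Age ≥ 18 is a
validation-level precondition of the survey, not a flow filter.

Non-users are partitioned by which clause family established their
indication: `sdu_only`, `partners_sti_hcv` (partner/condom and STI/HCV
clauses form one family), or `both`.

## Derived covariates

**Net equivalent income.** Income answer options are schema-driven
`(label, lower, upper)` bounds; the category value is the arithmetic
midpoint, except the open-ended top option which uses a fixed
population-weighted value (default 6,260 €/month). The value is divided by
√(household size) (square-root equivalence scale) and binned into six
bands, <1000€ through ≥5000€. The default schema is a 500-€ grid up to
5,000 €; real questionnaires can override it.

**HIV-specialist density.** Each federal state maps to a real-valued
density (specialists per 10,000 gay men) that is rounded to the nearest
integer (half up) and assigned to the integer-labelled band 0, 1–2, 3–5,
6–9 or 10–13. Rounding (rather than flooring) was chosen so that a state
at 5.6 falls in 6–9, matching the reading of the band labels as nearest
integer ranges; only the three city-state densities are published, so the
packaged full map is synthetic and marked as such.

**Encoding.** Grouped categories become binary indicators; the most
frequent category of each variable is the reference (ties broken by schema
order, for determinism). Missing values form a separate indicator per
variable by default; the `reference` mode instead lets missing rows
contribute to no indicator, the sensitivity variant in which "missing"
cannot reach significance. Constant (all-zero or all-one) columns are
excluded as inestimable. No standardization is applied: every predictor is
a 0/1 indicator, so the penalty already treats them symmetrically.

## Penalized model and selection

The model is a logistic regression with elastic-net penalty in the glmnet
parameterization,

    (1/n) Σᵢ ℓᵢ(β) + α·( λ·‖β‖₁ + (1−λ)/2·‖β‖₂² ),

fit with scikit-learn's saga solver (C = 1/(n·α), fixed `random_state`,
coordinate tolerance 1e-6 and an iteration cap that raises a convergence
error when hit). Because naming conventions for the two hyperparameters
differ between software traditions, the code calls λ the **mixing**
parameter (L1 share, grid 0.1 … 1.0) and α the **strength** throughout.

Tuning is two-stage:

1. Per mixing value, repeated stratified 15-fold cross-validation scores
   every strength on the grid by mean validation AUC (per-fold AUCs
   averaged; 5 repeats by default). The elbow is the one-standard-error
   rule: the largest (sparsest) strength whose mean AUC lies within one
   standard error (sd/√(folds·repeats) of the best row) of the maximum,
   ties going to the larger strength.
2. One model per mixing is refit on the full data at its selected
   strength; the final model minimizes lexicographically the number of
   non-zero coefficients, then AIC, then prefers the larger mixing (a pure
   determinism tie-break).

AIC is defined as 2(k+1) − 2·ℓ̂ with k = number of non-zero coefficients
and ℓ̂ the *unpenalized* log-likelihood at the penalized estimates — the
standard degrees-of-freedom result for lasso-type fits. The saga solver
can stop after a single epoch once the penalty zeroes every coefficient,
leaving the unpenalized intercept short of its conditional optimum; the
final fit therefore polishes the intercept with 1-D Newton steps at fixed
coefficients, which also makes the reported likelihoods well-defined.

Note that the lexicographic rule makes sparsity dominate: a mixing whose
one-SE strength empties the model entirely would win outright. That
cannot happen when any predictor carries signal — an empty model has
chance-level AUC and is excluded by the one-SE constraint — and is the
correct degenerate outcome on pure-noise data.

## Stratified bootstrap

The chosen model's hyperparameters are frozen and the fit is repeated on B
resamples drawn with replacement *within* each outcome class, preserving
the user/non-user split exactly (the outcome is the only variable the
procedure stratifies on). Per coefficient the summary reports the
full-data point estimate, the equal-tail percentile interval
(linear-interpolation quantiles) and a one-sided p-value

    p = (1 + #{replicates with opposite sign, or exactly 0}) / (B + 1),

with p = 1 when the point estimate is itself 0. Replicates shrunk exactly
to zero count **against** significance: the penalty concentrates mass at
zero, and counting it as non-support is the conservative convention (it is
consistent with an interval that touches 0.00 still being significant at
p < 0.05, since the percentile endpoint and the sign count apportion the
zero mass differently). The +1/(B+1) smoothing keeps p > 0 at finite B.
Replicates that fail to converge are dropped and counted; more than 1%
drops aborts the run. BCa or basic intervals are out of scope.

## Univariate barrier tests

Each reason for non-use is multi-select, so each is its own 2×2 table
(citing vs not, by stratum). The default test is the Yates
continuity-corrected χ²; when any expected cell count is below 5 the
two-sided Fisher exact test (probability-mass definition) is used. Both
choices were frozen only after recomputing every published p-value from
the published counts under both variants: the corrected χ² reproduces all
five printed chi-squared p-values at three decimals while the uncorrected
statistic reproduces none of them, and the probability-mass Fisher
definition matches the printed 0.062. Raw (unrounded) p-values are
Benjamini–Hochberg adjusted within the family of eight reasons.

For the indication stratification the test compares the two
single-criterion subgroups (partners/STI/HCV vs sexualized drug use); the
"both" column is displayed but excluded — including it as a 3-group test
does not reproduce the published values. For the density stratification
the bands 0–9 form the low stratum and 10–13 the high stratum; records
with an unknown state are excluded from the dichotomy.

Participation probabilities per federal state use the Wilson score
interval (well-behaved at counts of ten or fewer); bounds are snapped to
the exact 0/1 endpoints at k = 0 or k = n to remove floating-point noise.

## Synthetic cohorts

The generator draws each categorical covariate independently from
configurable marginals (the survey reports only marginals, so no
dependence structure is imposed; correlated designs would be a config
extension), assigns PrEP status from a logistic model on the sampled
values, draws each reason independently per non-user with stratum-specific
probability, and finally masks fields with per-variable missingness rates.
Each variable uses its own RNG stream keyed by (master seed, CRC32 of the
variable name), so editing one variable's config never shifts another's
draws, and identical (config, seed) gives byte-identical CSV output.

The packaged default config transcribes the published cohort summary's
marginals (age bands, origin, condom use, partner counts, drug use,
per-state counts, per-variable missing shares) and mirrors the published
effect directions in its outcome model; untabulated variables carry
plausible values for a German MSM online sample. Defaults, not assertions.
What the generator does **not** emulate: covariate correlations,
recruitment-channel and wave effects, within-person repeat participation
beyond a boolean flag, and informative (non-MCAR) missingness. Passing
tests therefore show the pipeline's correctness and stability, not that
the real data would yield the published coefficients.

## Validation study and problem sizes

Because the survey microdata are not public, the multivariable results are
validated on synthetic cohorts with known structure: n = 2,000, three
planted effects of |β| = 0.8 (drug use −, rural residence −, origin
outside Germany +) among ten null indicator columns, 50 seeds, B = 500
bootstrap samples per seed. Per seed the tuning uses the full mixing grid
with a shortened strength path (0.1, 0.03, 0.01, 0.003), one CV repeat and
a relaxed solver tolerance (1e-4) — about 650 penalized fits per seed,
which keeps the whole study in the minutes range on one CPU. Measured
quantities: the rate of recovering all three planted effects with correct
signs, the per-column false-inclusion rate, the rate of null-column
bootstrap p ≥ 0.05, path monotonicity and bit-for-bit determinism.

## Known limitations

* Strict active-set monotonicity along a strength path is *typical* but
  not guaranteed for exact elastic-net solutions: on rare draws a variable
  leaves the active set as the penalty weakens (the classical L1 drop
  step; confirmed on one study seed identically by two independent
  solvers). The strict form of that check can therefore fail without any
  implementation defect.
* The one-sided bootstrap p convention (zero replicates counting against
  significance, +1 smoothing) is a declared convention; other reasonable
  conventions shift borderline p-values.
* The income schema defaults and the non-city-state density map are
  placeholders; substantive runs on real data must supply both.
* The generator's independence assumptions make synthetic cohorts easier
  for variable selection than correlated real data; recovery rates here
  are an upper bound on what correlated designs would give.
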