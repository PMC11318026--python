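# Methods

## Data model and filtering

A census table has one row per shell: group ID, stratum (`surface` /
`basement`), intactness rating (percent of wall remaining, scored 30–100%
in 10% steps; anything below 30% is not a usable shelter and never enters
the table), entrance diameter (cm, to 0.1; the size proxy measurable even
on broken shells), and binary traits (smooth vs rough walls, encrusting
sponge, resident shrimp, resident crab). Occupants live in a second table,
one row per animal, with class (`dominant_male`, `subordinate_male`,
`female`, `juvenile`, or a heterospecific) and body size.

Usability filtering removes shells flagged as belonging to a live snail,
blocked by sediment or debris, or held by a heterospecific fish (those
shells are unavailable, never observed shared with conspecifics). Shrimp,
crab and sponge presence are covariates, not exclusions. The filter log
satisfies `rows_in = rows_out + sum(per-reason tallies)` exactly.

A shell shared by several conspecifics is one occupied shell for the
occupancy model; occupant-level analyses get one row per fish. Continuous
predictors are standardized (mean 0, sample SD with the n−1 denominator)
**on the usable table only**, and the stored constants are reused verbatim
everywhere downstream — in particular by every permutation refit, because
the index predicts for the same shells and per-permutation rescaling would
silently change the design.

## Occupancy GLMM

Binomial-logit model with one random intercept per social group (groups
choose only among their own shells, so shells within a group are not
independent). The marginal likelihood integrates the random intercept per
group; we use adaptive Gauss–Hermite quadrature: per group, Newton ascent
finds the mode of the joint log-density in `u`, the integrand is
re-centered there and scaled by the curvature, and a 15-node probabilists'
Hermite rule integrates it. On grouped binary data of this size the
15-node rule agrees with a 10,001-point trapezoid integral to ~1e-13 and
with a 25-node rule to well under 1e-4 (both asserted in tests).

Numerical choices:

* `sigma` is optimized on the log scale (L-BFGS-B over `(beta, log
  sigma)`, numerical gradients, `ftol` 1e-12, `gtol` 1e-6, max 500
  iterations) with a boundary guard: if `log sigma` hits its floor the fit
  is reported as the plain-logistic limit with `sigma = 0`, whose
  estimates match IRLS to <1e-3 (tested against statsmodels GLM).
* Standard errors come from the numerically differentiated (central
  differences, relative step 1e-5) Hessian of the negative marginal
  log-likelihood over `(beta, log sigma)`; the `beta` block of its inverse
  is the reported covariance, so fixed-effect SEs account for variance
  uncertainty.
* Treatment coding with references: basement, rough walls, absence of a
  trait, dominant male. Interactions are limited to two-way products of
  declared main effects.
* A complete-separation guard warns whenever any |beta| exceeds 10 on the
  scaled design; such estimates are unbounded MLEs drifting along a
  likelihood plateau and their numerical values are optimizer artifacts.
* Predictions are conditional on the estimated group intercepts
  (`expit(x'beta + u_g)`), not population-averaged; rows from groups not
  seen in fitting are an error. Conditional prediction is what the index
  needs: a shell is ranked within its own group's opportunity set.

Interaction screening follows the analysis protocol: each candidate
interaction (location×intactness, location×entrance, intactness×entrance)
is kept iff the LRT against the main-effects model has p < 0.05. At the
default generating conditions the intactness×location interaction (0.66
log-odds per SD) has SE ≈ 0.30, so screening detects it in only ~55–65% of
replicates — retention is genuinely data-driven, and pipeline runs that
drop it are expected behavior, not failures.

Pairwise Wald contrasts for a categorical fixed effect use contrast
vectors on the treatment-coded estimates with unadjusted two-sided normal
p-values. Collinearity is checked with generalized VIFs via the
determinant-ratio formulation on the design-column correlation matrix.

## Occupant-class multinomial

Baseline-category logit over the four conspecific classes, one row per
fish carrying its home shell's covariates, fit by Newton–Raphson with
step-halving from a zero start (gradient max-norm < 1e-6). Group identity
enters as fixed-effect dummies. Following the analysis protocol the class
model omits crab and sponge presence (too rare among occupied shells) and
the intactness×location interaction.

Groups with few occupants can separate their dummies; the fit warns when
any |gamma| > 15 and offers an optional ridge (default 1e-4) on the
dummy columns only, off by default so the default fit is the unpenalized
likelihood. Releveling uses the linear identity `gamma_{a|b} = gamma_{a|c}
- gamma_{b|c}` with the covariance mapped through the same linear
transform; releveled coefficients agree with a genuine refit to <1e-4.

**Known limitation — incidental-parameter bias.** With ~250 occupant rows
and 3×40 group-dummy parameters, the maximum-likelihood slopes are
inflated in magnitude by roughly 40% (a Neyman–Scott effect): recovery
simulations that generate classes from the default coefficients (group
effects zero) and refit with dummies return a dominant-vs-juvenile
entrance coefficient near −3.3 rather than the generating −2.26, while the
same fit without dummies returns ≈ −2.38. The tiny dummy ridge does not
change this. Consequently the group-dummy recovery study reports what the
prescribed fit produces, and the fitter's correctness is instead
established by (a) exact agreement with statsmodels MNLogit on identified
coefficients, and (b) a recovery test at ~1000 pooled rows without
nuisance dummies, which is unbiased to within Monte-Carlo error.

## Resource attractiveness index

For each shell: (1) fit the final occupancy model and take its conditional
prediction `p_obs`; (2) for r = 1..n_rand, permute the occupancy labels
within each group — permutation without replacement, so each group's
occupied count is conserved — refit the same specification to the permuted
labels, and predict; (3) average the replicate predictions into `p_null`;
(4) `a_raw = p_obs − p_null`; (5) standardize `a_raw` within group (mean
0, sample SD 1; the n−1 denominator, switchable). Refitting is essential:
without it the prediction is a function of covariates only and the
subtraction would be identically zero (exposed as `refit=False` for
demonstration).

Replicate r's permutation is a pure function of `(seed, r)`, so any
replicate can be replayed in isolation; the refits warm-start from the
previous successful replicate's estimates (all replicates are draws from
the same null) and skip standard errors. Refits that fail to converge are
skipped and tallied; more than 5% failures aborts the run. Single-shell
and zero-variance groups receive missing `z` with a per-shell flag
(strict mode turns flags into errors).

Calibration: when occupancy is generated with all covariate effects zero,
the observed labelling is exchangeable with the permuted ones, so `a_raw`
is pure Monte-Carlo noise — per shell it stays within ~3 SE of the
permutation spread, and group-mean `p_null` tracks each group's occupied
fraction up to random-intercept shrinkage (prior SD 0.5 against ~25
Bernoulli observations shrinks deviations roughly by half). Both are
asserted in tests at `n_rand = 200`.

## Synthetic censuses

The generator draws, per configuration (defaults in parentheses): group
count (41); shells per group from a negative binomial matched to mean 25.8
and SD 15.8, redrawn into [4, 76]; entrance size from Normal(2.00, 0.22)
cm redrawn into [1.1, 2.7] and rounded to 0.1; intactness from
Normal(76.7, 23.0) rounded to the nearest 10 and clipped to [30, 100] (the
field distribution's shape beyond mean/SD/median/range is unknown; the
rounded normal is an explicit stand-in isolated behind the config);
surface with probability 775/1057; smooth 0.072; sponge 0.046; shrimp
43/1057; crab 35/1057. Covariates are mutually independent, matching the
near-zero observed entrance–intactness correlation.

Occupancy comes from the logistic random-intercept model with generating
slopes equal to the occupancy-model estimates (intactness 1.21, entrance
0.17, intactness×surface 0.66, shrimp −0.93, crab −1.94, sponge −0.98,
smooth −0.43; the location main effect is unreported and defaults to 0),
`sigma = 0.5` (also unreported; recovery targets are slopes, which are
insensitive to it), and an intercept solved numerically so the expected
marginal occupancy is 226/1057 ≈ 0.214. Occupant classes are then drawn
per occupied shell from the baseline-category logit with the class-model
coefficients (group effects zero); body sizes are decorative draws from
the class-specific size distributions.

What the generator does **not** emulate: group composition constraints
(exactly one dominant male, bounded female/juvenile counts), multi-occupant
shells, spatial shell arrangement, and any size-matching between fish and
shell. Passing recovery tests therefore certify the estimators under the
stated sampling model, not those richer features of real censuses.

Recovery studies regenerate censuses at the defaults and refit; replicates
whose occupancy fit trips the separation guard are excluded from the
averages, because a separated MLE has no finite value to average — at the
default crab prevalence (3.3%) about 14% of tables contain no occupied
crab shell, making the crab coefficient unbounded. With that exclusion
the 200-replicate means recover all four tracked slopes to within their
Monte-Carlo error.

## Problem sizes and determinism

Default study sizes: 41-group censuses (~1050 shells), 200 replicates for
occupancy recovery, 100 for the multinomial study, `n_rand` = 1000 for a
production index run (tests and the example analysis use 200–300, which
changes `z` by well under the permutation MC error; a doubling-stability
check is asserted in tests). Every random draw descends from a single
master seed through named child streams (`SeedSequence([seed, ...])`), so
pipeline runs are byte-identical given the same configuration and any
permutation replicate can be replayed alone. All artifacts are plain
TSV/CSV/JSON.
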