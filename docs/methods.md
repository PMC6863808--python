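# Methods

## The model

`mixirt` works with finite mixtures of adjacent-category logit models for
ordered rating-scale responses — the family that contains the mixed partial
credit model (mPCM) and the restricted mixed generalized partial credit
model (rmGPCM). For a respondent in latent class *g* with standard-normal
trait draw *z*, the log-odds of choosing category *c* over *c−1* of item *i*
is

    log P(X_i = c) / P(X_i = c−1) = Δβ_{gic} + λ_i · λ_g · z ,

with categories coded 0…C−1. The Δβ (delta-beta) parameters are
class-specific adjacent-category intercept differences; λ_i is an item
discrimination, fixed across classes and with λ_1 = 1 for identification
(all λ_i = 1 in the mPCM); λ_g scales the trait within class *g*; class
membership follows a multinomial logit with the first class as the
reference (logit 0). The equivalent IRT threshold form is
τ_{gis} = −Δβ_{gis}/λ_i, so unordered thresholds (avoided categories)
appear as sign patterns in the delta-betas. The marginal likelihood
integrates the trait per class on a quadrature grid and sums over classes.

Two readings of λ_g circulate for this kind of model: a loading (the
within-class trait SD) or the trait variance itself. The package defaults
to the loading reading; `ModelSpec(trait_scale_is_variance=True)` selects
the variance reading. The loading reading is the default because, with the
shipped generating parameters, it reproduces the population model's
mean classification probabilities and coverage behaviour, while the
variance reading does not.

## Population parameters and the simulation design

`mixirt.simulate` ships the generating parameters of two three-class
population models (rmGPCM-3 and mPCM-3; 5 items, 11 categories) in
`data/generating_parameters.csv`, checksum-verified at load. They derive
from an empirical application to a short job-satisfaction scale with an
11-point response format, and encode three response-style classes: an
extreme-responding class, an ordinary-responding class, and a partial
extreme-responding class. Three cells of that table were typographically
ambiguous in the source; they are flagged `low_confidence` in the CSV and
resolved so that every (class, item) row has exactly five marked steps.

`derive_condition` produces every cell of the 2 (model) × 2 (5/15 items) ×
2 (11/6 categories) × 2 (3/2 classes) design: 15-item tests replicate the
five base items three times; 6-category tests keep the five marked steps of
each item in their original order; 2-class mixtures keep classes 1–2 with
class logits (0, 0.75). `generate_dataset` then draws, per respondent, a
class from the multinomial logit, a trait *z* ~ N(0,1), and item responses
from the category probabilities at λ_g·z. The generator emulates complete,
independent rating-scale responses; it does not emulate survey weights,
missing data, panel attrition or local item dependence, so passing tests
speak to estimator behaviour under the model, not to robustness against
those real-data features.

Per-replication seeds are `base_seed XOR CRC32(condition_id:replication)`,
truncated to 31 bits, so replications are independent work units and any
scheduling order reproduces identical results.

## Estimation

Marginal maximum likelihood with the trait integrated on 80 probabilists'
Gauss–Hermite points (renormalized to sum to 1; a rectangular grid is
available for cross-checks). Estimation is staged:

1. **Generalized EM.** The E-step computes joint posteriors over
   (class, node). The M-step updates class logits in closed form and takes
   one damped Newton step per parameter block — the 10 delta-betas of each
   (class, item) jointly, then each free discrimination, then each trait
   scale — on the expected complete-data log-likelihood, with step-halving
   so no block update can lower it. The objective is therefore
   non-decreasing across iterations. Defaults: at most 10,000 iterations,
   stop when the absolute objective change falls below 0.01.
2. **Quasi-Newton refinement.** L-BFGS-B on the same objective with the
   analytic gradient (Fisher's identity: the marginal score equals the
   posterior-expected complete-data score), bounds |Δβ| ≤ 50, λ_i ≥ 1e−3,
   λ_g ≥ 1e−4, at most 600 iterations. Convergence is declared when the
   gradient max-norm falls below 1e−8·(1+|objective|). The refinement never
   returns a worse objective than its input; on failure the EM solution is
   kept with `nr_converged=False`.
3. **Multiple starts.** `multi_start_fit` runs 200 EM iterations from each
   of 100 random start sets (delta-betas U(−2,2), discriminations
   log-U(0.5,2), class logits U(−1,1), trait scales U(0.1,1) — spanning the
   population table's range) plus, when configured, a warm start at the
   generating values, then continues the best candidate to convergence and
   refines it. In the study runner the true-class-count model is
   warm-started at the generating values, which is also what prevents
   label switching across replications.

**Smoothing.** By default the objective adds a small smoothing prior
(`FitConfig.prior_strength = 1.0`): one pseudo-observation per item
response table, spread over classes and the trait grid and distributed over
categories in proportion to the item's *observed marginal* distribution,
plus one pseudo-observation over the class sizes. This mirrors the default
Bayes constants of the widely used commercial implementation of these
models. It matters: with 11 response categories, many class-conditional
cells have near-zero expected frequency, their delta-betas are essentially
unidentified, and the unpenalized MLE sends dozens of coordinates per
replication beyond |10| at N = 500. The marginal-proportional prior pins
such cells near the marginal log-ratios while perturbing well-identified
coordinates negligibly. `prior_strength = 0` gives pure ML. `FitResult`
reports both the raw marginal log-likelihood (`loglik`, used by the
information criteria) and the penalized `objective`.

**Standard errors.** Observed information by central finite differences of
the analytic score (step 1e−5·(1+|θ|)), symmetrized. The information is
inverted on its well-determined eigenspace: eigenvalues below 1e−8 of the
largest are treated as null directions, and coordinates loading on them
(|eigenvector entry| > 0.5) are flagged as boundary, as are SEs above 1e4
and parameters at their clamp. An OPG (outer product of per-respondent
scores) alternative is available. A solution with strictly more than 10%
boundary-flagged SEs is *improper* and is dropped from accuracy and
selection analyses.

## Accuracy battery

Computed across label-aligned replications against the generating values,
after trimming: estimates beyond |10|, SEs above 50, and boundary-flagged
SEs are removed pairwise (parameter and SE together).

* RMdSE = sqrt(Md((p̂−p)²)) per coordinate, median-aggregated over the
  coordinates of a parameter type within a class;
* SE bias = Md(|ŝe − SD(p̂)|), with the empirical SD using the n−1
  denominator over non-excluded estimates;
* median CI width = Md(2·1.959964·ŝe) (the z-quantile is fixed at
  1.959964 for bit-stable output);
* coverage = share of replications whose 95% CI contains the truth,
  mean-aggregated within a type and class;
* Spearman concordance: per replication and item, the rank correlation
  (average-rank ties) between generating and estimated delta-betas over
  the non-excluded steps, averaged over items then replications, per class.

Class-size accuracy is computed on the multinomial-logit scale (reference
class excluded), matching the scale of the population table; a
proportion-scale variant can be derived from the exported estimates.

## Class enumeration

AIC, BIC, CAIC, AIC3 and SABIC (natural logs). SABIC uses Sclove's
ln((N+2)/24) penalty; the `sabic_literal` switch exposes a ln(N+224)
variant for audit, which is numerically indistinguishable from BIC and not
useful as a sample-size adjustment. The smallest criterion value wins; ties
break toward fewer classes; improper candidate solutions are excluded from
each replication's argmin, and replications whose true-count solution is
improper are dropped wholesale. A criterion is deemed reliable in a
condition when it recovers the true class count in at least 95% of
replications.

## Problem sizes

The full published design (500 replications × 10 sample sizes × 2 models,
100 start sets each) is cluster-scale. The package's study runner defaults
to 50 replications and 10 random start sets plus the warm start;
`scripts/acceptance.py` runs the challenging cell at 50 warm-started
replications for N = 500 and N = 2,500, and the test suite uses 12 and 10
replications for the same checks. These are the package's own desk-scale
defaults; all of them are single flags away from the full-scale settings.

## Numerical choices and degenerate inputs

Category probabilities are computed from cumulative step logits via
log-sum-exp and floored at 1e−300 before logs. Empty-class posteriors
(total mass < 1e−8) flag the fit as degenerate but do not abort. All-flat
response data drives the affected delta-betas toward the clamp and their
SEs to boundary flags. Label alignment minimizes the summed squared
delta-beta differences over all class permutations (exhaustive, G! ≤ 24)
and re-references class logits after permutation; permuted class-logit SEs
are exact only under the identity permutation. The multinomial-logistic
label-separation certificate uses moderate regularization (C = 1) because
an unregularized fit can linearly separate even a deliberately mislabeled
replication in the 50-dimensional feature space.

## Known limitations

* The refinement stage is quasi-Newton; it needs many more (cheap)
  iterations than a full Newton implementation, and its convergence rates
  are not comparable with published Newton–Raphson convergence
  percentages, which are implementation-specific.
* Per-item Spearman concordance of within-replication estimates is bounded
  by the information limit: generating tables with near-tied steps inside
  an item (differences of 0.01 logits) force occasional rank inversions at
  any realistic N, so concordance near 1.0 is only reachable once the
  trimming rules have removed the ill-identified coordinates.
* Trait (person-parameter) scoring, Bayesian estimation and covariate
  extensions are out of scope.
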