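# Methods notes

## Model family

All models are arm-based binomial-logit NMA models for dichotomous
outcomes. For arm *k* of study *i*: `r_ik ~ Binomial(p_ik, n_ik)`,
`logit(p_ik) = mu_i + delta_ik`, `delta_i,baseline = 0`. The per-study
baselines `mu_i` are nuisance parameters with independent vague normal
priors; nothing is modelled about absolute event rates.

- **Consistency** models express every contrast through the basic
  parameters `d_2..d_K` (log odds ratio of each treatment against the
  reference, `d_1 = 0`), assuming direct and indirect evidence agree
  (`d_AC = d_AB + d_BC`).
- **Inconsistency (UME)** models give each *observed* baseline-relative
  comparison its own independent mean effect. Multi-arm trials contribute
  comparisons relative to their own baseline arm only, so a design like
  A-B-D adds parameters AB and AD but not BD. The UME model is a fit
  benchmark, not an estimation model: comparing its DIC and per-point
  posterior mean deviances with the consistency fit (the dev–dev table)
  localizes potential inconsistency.
- **Random effects** place the non-baseline `delta` vector of each study
  on a multivariate normal with mean given by the framework above,
  variance `sigma^2`, and pairwise covariance `sigma^2 / 2` — the
  homogeneous exchangeable structure that makes multi-arm trials
  internally coherent. A single `sigma` is shared across comparisons in
  both frameworks. Fixed-effect models set `delta` to its mean.

Assumptions worth stating: one outcome per analysis; trials are
exchangeable given treatment set; heterogeneity variance is common to all
comparisons; the evidence network must be connected (enforced at load
time).

## Priors

- Baselines and effect parameters: `Normal(0, sd = 100)` (variance 1e4) on
  the log-odds / log-odds-ratio scale. At sd 100 the prior is flat over
  any plausible odds ratio; the value is configurable in `PriorConfig`.
- Heterogeneity, vague default: `sigma ~ Uniform(0, 2)`. On the log-OR
  scale, sigma = 2 already allows studies to disagree by a factor of ~50
  in odds, so the bound is not restrictive for mortality-type outcomes.
- Heterogeneity, informative: lognormal priors on `sigma^2` in the style
  of Turner et al. (2012, Int J Epidemiol 41:818-827), keyed by
  (outcome category, comparison category). The bundled table carries
  three commonly quoted rows transcribed by the package authors
  (all-cause mortality, semi-objective, subjective — each vs
  placebo/control); it is deliberately a plain editable dict and users
  analysing other settings should verify entries against the primary
  source. The density is parameterized on sigma with the `2*sigma`
  Jacobian so that `log_prior` is a proper density on the sampled scale
  (verified by numerical integration in the tests).

## Zero cells

Bayesian binomial likelihoods tolerate occasional zero cells, so the
default is **no correction** (the bundled example is analysed uncorrected,
matching its source analysis). When requested, the adjusted continuity
correction adds `c_a` events and `2*c_a` patients to *every* arm of any
study containing a zero-event or all-event cell, with `c_a` proportional
to the reciprocal of the mean size of the study's other arms and
normalized so the per-study corrections sum to `n_arms / 2`. This makes
the correction exactly 0.5 per arm for equal-sized arms and shifts weight
toward the smaller arm otherwise (the Sweeting-style treatment-arm
correction, generalized to multi-arm studies via the mean of the other
arms). Corrected counts are fractional and are kept fractional: the
likelihood uses the log-Gamma continuous extension of the binomial mass,
so nothing needs rounding. The correction is *not* idempotent by design —
it acts on the zero cells present in the data it is given; applying it to
a dataset without zero/all-event cells is the identity. All studies are
kept, including all-zero studies (flagged with a warning, since they carry
no information about relative effects), and fit statistics computed on
corrected data emit a caution because corrections make residual deviances
look better than the raw data warrant.

## Sampler

Adaptive random-walk Metropolis-within-Gibbs. Scalar blocks: each `mu_i`,
each effect parameter, each `delta_ik`, and `sigma`. Per-block Gaussian
step sizes adapt every 100 iterations during burn-in toward an acceptance
rate of 0.44 (the scalar-proposal optimum) and are frozen afterwards, so
the retained draws come from a fixed Markov kernel targeting the exact
posterior. Two additional symmetric random-walk blocks dramatically reduce
autocorrelation in the random-effects models:

- a **translation** block per effect parameter that moves `d_j` and the
  `delta_ik` whose prior means depend on it by the same amount, leaving
  the random-effects residuals (and hence their density) unchanged — only
  the affected arms' likelihood and the `d_j` prior enter the ratio;
- a **rescaling** block that multiplies `sigma` and all residuals
  `delta - mean` by a common `exp(eps)`, leaving the residual z-scores
  invariant (the acceptance ratio picks up the likelihood change, the
  sigma prior, and a `log`-scale Jacobian `+eps`).

Both are standard interweaving-style moves on linear subspaces of the
parameter space; they change mixing, not the target. With them, the
default run satisfies the MC-error rule (below) with a wide margin.

Initial values: `mu` and `d` uniform on configurable ranges (default
(-2, 2), i.e. baseline risks ~12-88% and odds ratios ~0.14-7.4), `delta`
at its conditional means, `sigma` uniform over the central half of its
prior support. Initialization retries (up to 50) if the posterior is not
finite at the start. Everything is deterministic given
`(base_seed, chain)`; chains use disjoint seed strings so no two
(seed, chain) combinations collide.

Defaults: 3 chains, 20,000 burn-in, 40,000 retained, thin 1. On the
bundled 12-trial network this takes ~25 s on one core and yields MC
errors ≤ 2.3% of the posterior sd for every effect parameter and sigma.

## Diagnostics

- **PSRF**: the classic within/between-variance potential scale reduction
  factor `sqrt(((n-1)/n * W + B/n) / W)` on retained draws, per monitored
  quantity; constant chains raise an error rather than return a number.
  The interval-based Brooks-Gelman refinement is out of scope.
- **MC error**: batch means over the concatenated chains with 50 batches
  (trailing remainder dropped). The convergence report checks
  MC error < 5% of the posterior sd for every effect parameter and sigma;
  `overall_pass` is the conjunction.
- **Residual deviance / DIC**: per-data-point binomial saturated deviance
  with the `0*ln(0) = 0` convention; `Dbar` is its posterior mean,
  `Dhat` evaluates at the posterior means of the per-arm probabilities
  (probability-scale plug-in, the convention for arm-based binomial
  models), `pD = Dbar - Dhat`, `DIC = Dbar + pD`. Per-point deviances sum
  to `Dbar` exactly by construction.

## Reporting conventions

- Posterior summaries pool all chains; quantiles use linear interpolation
  between order statistics (numpy's default; on draws 1..100 the 95%
  interval is (3.475, 97.525)).
- Rankings: per draw, treatments are ordered by their basic parameter —
  ascending when the outcome is "bad" (fewer events better), descending
  when "good"; ties (measure-zero for continuous posteriors) break by
  treatment index. SUCRA is the mean cumulative rank probability over
  ranks 1..K-1; across treatments SUCRA always averages to 0.5, and
  reversing the outcome direction reverses the ordering exactly.
- League table: diagonal ordered by descending SUCRA; `cell(row, col)` is
  the OR of the row treatment vs the column treatment, read top-to-bottom
  then left-to-right, and the convention is printed in every export.
  Cell medians and CrI bounds are exponentiated log-scale quantiles, so
  `cell(i,j) * cell(j,i) = 1` holds exactly.
- Network layout: circular; node radius proportional to
  `sqrt(participants)` (area encodes sample size), edge width linear in
  the number of trials.
- Outcome direction never touches the likelihood — only ranking and
  presentation.

## Simulator

`simulate_dataset` is the forward version of the random-effects
consistency model: uniform baseline log-odds, jointly drawn multi-arm
`delta` (using the explicit exchangeable covariance, *not* the sampler's
conditional chain — keeping the generator an independent check of that
decomposition), binomial events. It emulates balanced randomized trials
with known truth; it does not emulate real-data features such as
study-level effect modifiers, informative arm sizes, selective reporting,
or non-exchangeable heterogeneity. Passing recovery tests therefore shows
the estimation machinery is correct under the model's own assumptions —
not that the model is right for any particular real network. An optional
scalar `inconsistency_bump` offsets one designated comparison to create
genuine loop inconsistency for dev-dev exercises.

## Problem sizes used in the test suite

Unit tests run on toy networks (1-3 studies) and short chains. The
end-to-end checks use: the full default run (3 chains, 20k + 40k) for the
reproduction of the published odds ratios; 3 chains x 10k draws against
dense grid integration for sampler correctness (the two-treatment
fixed-effect posterior is integrated exactly on a per-study 1-D grid,
since the baselines factorize given d_2); and 20 replicate simulated
networks of 30 studies (arms of 200-400, true sigma 0.3) fitted with 2
chains x (2k burn-in + 4k retained) for parameter recovery. These sizes
were chosen so the whole suite stays in the couple-of-minutes range while
each check retains enough Monte Carlo precision for its tolerance.

## Limitations

- Binomial-logit outcomes only: no continuous, rate or survival
  likelihoods, and no meta-regression covariates.
- Inconsistency assessment is global (UME comparison); node-splitting is
  not implemented.
- The informative-prior table ships with a minimal transcription; users
  should extend it from the primary source for their own outcome types.
- The sampler is serial; for very large networks (dozens of treatments,
  hundreds of studies) a gradient-based sampler would be preferable.
- The 15-treatment / 50-study caps of the classic spreadsheet workflow
  are kept only as warnings — they are interface lore, not statistics.
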