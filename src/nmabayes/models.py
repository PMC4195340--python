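"""Binomial-logit network-meta-analysis models.

The model family follows the standard Bayesian arm-based formulation for
dichotomous outcomes: for arm k of study i,

    r_ik ~ Binomial(p_ik, n_ik),      logit(p_ik) = mu_i + delta_ik,

with delta = 0 on each study's baseline arm.  Under the *fixed-effect*
structure delta_ik = m_ik is deterministic; under *random effects* the
non-baseline delta_i vector is multivariate normal with mean m_i,
variances sigma^2 and pairwise covariances sigma^2/2 (the homogeneous
exchangeable structure that accounts for the correlation between arms of
multi-arm trials).

The mean m_ik depends on the framework:

* consistency: m_ik = d[t_ik] - d[t_i1] with d_1 = 0 — all contrasts
  derive from the K-1 basic parameters;
* inconsistency (unrelated mean effects, UME): one free parameter per
  observed (study-baseline, non-baseline) treatment pair, so direct
  comparisons are not pooled through the network.

Fractional event counts (continuity-corrected data) are handled by the
log-Gamma continuous extension of the binomial log-mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import ModelError
from .data import ModelArrays, NMADataset, prepare_model_arrays
from .priors import PriorConfig, vague_priors

#: logit values are clamped to +-_LOGIT_CLAMP so a structural zero cell under
#: an extreme state yields a large negative but finite log-likelihood.
_LOGIT_CLAMP = 500.0

_LOG_SQRT_2PI = 0.5 * math.log(2 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Effect structure x framework x priors x outcome direction.

    ``direction`` ("bad" or "good") states whether higher event
    probabilities harm the patient (e.g. death) or help (e.g. survival);
    it affects ranking and reporting only, never the likelihood.
    """

    effect: str = "random"             # "fixed" | "random"
    framework: str = "consistency"     # "consistency" | "inconsistency"
    priors: PriorConfig = field(default_factory=vague_priors)
    direction: str = "bad"             # "bad" | "good"

    def __post_init__(self) -> None:
        if self.effect not in ("fixed", "random"):
            raise ModelError(f"unknown effect structure {self.effect!r}")
        if self.framework not in ("consistency", "inconsistency"):
            raise ModelError(f"unknown framework {self.framework!r}")
        if self.direction not in ("bad", "good"):
            raise ModelError(f"unknown outcome direction {self.direction!r}")
        if (
            self.effect == "fixed"
            and self.priors.heterogeneity.kind == "lognormal"
        ):
            raise ModelError(
                "informative heterogeneity priors are only meaningful for "
                "random-effects models"
            )

    @property
    def is_random(self) -> bool:
        return self.effect == "random"

    @property
    def is_ume(self) -> bool:
        return self.framework == "inconsistency"


@dataclass(frozen=True)
class ParameterState:
    """One point in parameter space.

    ``d`` holds the K-1 basic parameters (consistency; d_1 = 0 implicit)
    or the per-comparison mean effects (inconsistency).  ``delta`` holds,
    per study, the non-baseline trial-specific log odds ratios (random
    effects only).  ``sigma`` is the between-study sd (random effects only).
    """

    mu: tuple[float, ...]
    d: tuple[float, ...]
    delta: tuple[tuple[float, ...], ...] | None = None
    sigma: float | None = None


def ume_parameterize(data: NMADataset | ModelArrays) -> tuple[tuple[int, int], ...]:
    """Observed baseline-relative comparison pairs, sorted.

    One independent mean-effect parameter exists per distinct
    (study-baseline treatment, non-baseline treatment) pair; multi-arm
    trials contribute pairs relative to their own baseline arm only.
    """
    arrays = data if isinstance(data, ModelArrays) else prepare_model_arrays(data)
    pairs: set[tuple[int, int]] = set()
    for t in arrays.t:
        base = t[0]
        for other in t[1:]:
            pairs.add((base, other))
    return tuple(sorted(pairs))


def n_effect_parameters(spec: ModelSpec, arrays: ModelArrays) -> int:
    if spec.is_ume:
        return len(ume_parameterize(arrays))
    return arrays.n_treatments - 1


def effect_prior_means(
    state_d, spec: ModelSpec, arrays: ModelArrays
) -> list[list[float]]:
    """Per study, the mean m_ik of each non-baseline delta (see module doc)."""
    if spec.is_ume:
        comp_index = {pair: c for c, pair in enumerate(ume_parameterize(arrays))}
        return [
            [state_d[comp_index[(t[0], other)]] for other in t[1:]]
            for t in arrays.t
        ]
    def dval(t: int) -> float:
        return 0.0 if t == 1 else state_d[t - 2]
    return [[dval(other) - dval(t[0]) for other in t[1:]] for t in arrays.t]


# ---------------------------------------------------------------------------
# likelihood & priors

def binomial_logpmf(r: float, n: float, x: float, log_binom_coef: float | None = None) -> float:
    """log Binomial(r | n, expit(x)) via the log-Gamma continuous extension.

    ``x`` is the logit of the event probability and is clamped so the
    result is always finite.
    """
    if log_binom_coef is None:
        log_binom_coef = (
            math.lgamma(n + 1) - math.lgamma(r + 1) - math.lgamma(n - r + 1)
        )
    x = max(-_LOGIT_CLAMP, min(_LOGIT_CLAMP, x))
    if x >= 0:
        log_p = -math.log1p(math.exp(-x))
        log_1mp = -x + log_p
    else:
        log_p = x - math.log1p(math.exp(x))
        log_1mp = log_p - x
    return log_binom_coef + r * log_p + (n - r) * log_1mp


def _deltas(state: ParameterState, spec: ModelSpec, arrays: ModelArrays):
    means = effect_prior_means(state.d, spec, arrays)
    if spec.is_random:
        if state.delta is None:
            raise ModelError("random-effects state requires delta")
        if tuple(len(dd) for dd in state.delta) != tuple(na - 1 for na in arrays.na):
            raise ModelError("delta dimensions do not match arrays")
        return [list(dd) for dd in state.delta], means
    return means, means


def log_likelihood(arrays: ModelArrays, state: ParameterState, spec: ModelSpec) -> float:
    """Sum of binomial log-masses over every data point (arm)."""
    if len(state.mu) != arrays.n_studies:
        raise ModelError("mu dimension does not match number of studies")
    if len(state.d) != n_effect_parameters(spec, arrays):
        raise ModelError("d dimension does not match model parameterization")
    deltas, _ = _deltas(state, spec, arrays)
    total = 0.0
    for i in range(arrays.n_studies):
        mu_i = state.mu[i]
        total += binomial_logpmf(arrays.r[i][0], arrays.n[i][0], mu_i)
        for k in range(1, arrays.na[i]):
            total += binomial_logpmf(
                arrays.r[i][k], arrays.n[i][k], mu_i + deltas[i][k - 1]
            )
    return total


def fitted_probabilities(
    arrays: ModelArrays, state: ParameterState, spec: ModelSpec
) -> np.ndarray:
    """Per-data-point event probabilities in study-major arm order."""
    from scipy.special import expit

    deltas, _ = _deltas(state, spec, arrays)
    out = []
    for i in range(arrays.n_studies):
        out.append(state.mu[i])
        out.extend(state.mu[i] + d for d in deltas[i])
    return expit(np.asarray(out))


def conditional_delta(
    state: ParameterState,
    spec: ModelSpec,
    arrays: ModelArrays,
    study: int,
    arm_position: int,
) -> tuple[float, float]:
    """Conditional normal for delta at ``arm_position`` given earlier arms.

    Under the exchangeable structure (variance sigma^2, covariance
    sigma^2/2), conditioning delta_ik on delta_i2..delta_i(k-1) gives

        mean = m_ik + (1/(k-1)) * sum_{j<k} (delta_ij - m_ij)
        var  = sigma^2 * k / (2 (k-1))

    with ``arm_position`` k counted 1-based from the baseline arm (so the
    first non-baseline arm is k = 2 and recovers the unconditional
    sigma^2).
    """
    if not spec.is_random:
        raise ModelError("conditional_delta applies to random-effects models")
    if arm_position < 2:
        raise ModelError("baseline arm carries no delta")
    k = arm_position
    _, means = _deltas(state, spec, arrays)
    m = means[study]
    if k - 1 > len(m):
        raise ModelError("arm position beyond study size")
    sigma = state.sigma if state.sigma is not None else 0.0
    mean = m[k - 2]
    if k > 2:
        resid = sum(state.delta[study][j] - m[j] for j in range(k - 2))
        mean += resid / (k - 1)
    var = sigma * sigma * k / (2.0 * (k - 1))
    return mean, var


def log_random_effects(
    state: ParameterState, arrays: ModelArrays, spec: ModelSpec
) -> float:
    """Joint log-density of the trial-specific deltas given (d, sigma).

    Per study the non-baseline delta vector (dimension m) is multivariate
    normal with covariance Sigma = (sigma^2/2)(I + J); the closed forms
    |Sigma| = (sigma^2/2)^m (m+1) and
    Sigma^{-1} = (2/sigma^2)(I - J/(m+1)) avoid any linear algebra.
    """
    if not spec.is_random:
        return 0.0
    sigma = state.sigma
    if sigma is None or sigma <= 0:
        return -math.inf
    deltas, means = _deltas(state, spec, arrays)
    s2 = sigma * sigma
    total = 0.0
    for i in range(arrays.n_studies):
        m = arrays.na[i] - 1
        x = [deltas[i][j] - means[i][j] for j in range(m)]
        sx = sum(x)
        q = (2.0 / s2) * (sum(v * v for v in x) - sx * sx / (m + 1))
        logdet = m * math.log(s2 / 2.0) + math.log(m + 1)
        total += -0.5 * (m * math.log(2 * math.pi) + logdet + q)
    return total


def _normal_logpdf(x: float, sd: float) -> float:
    return -_LOG_SQRT_2PI - math.log(sd) - 0.5 * (x / sd) ** 2


def log_prior(state: ParameterState, spec: ModelSpec) -> float:
    """Log prior over mu, d (or per-comparison effects) and sigma."""
    p = spec.priors
    total = sum(_normal_logpdf(m, p.baseline_sd) for m in state.mu)
    total += sum(_normal_logpdf(d, p.effect_sd) for d in state.d)
    if spec.is_random:
        if state.sigma is None:
            raise ModelError("random-effects state requires sigma")
        total += p.heterogeneity.log_density_sigma(state.sigma)
    return total


def log_posterior(arrays: ModelArrays, state: ParameterState, spec: ModelSpec) -> float:
    """log_likelihood + log_random_effects + log_prior."""
    lp = log_prior(state, spec)
    if lp == -math.inf:
        return -math.inf
    return log_likelihood(arrays, state, spec) + log_random_effects(
        state, arrays, spec
    ) + lp


# ---------------------------------------------------------------------------
# derived quantities

def consistency_or(draws, i: int, j: int) -> np.ndarray:
    """Per-draw odds ratio of treatment ``j`` versus treatment ``i``.

    Under consistency every contrast derives from the basic parameters:
    OR_{j vs i} = exp(d_j - d_i) with d_1 = 0.  ``draws`` is a
    :class:`~nmabayes.sampler.PosteriorDraws` from a consistency fit.
    """
    if getattr(draws, "spec", None) is not None and draws.spec.is_ume:
        raise ModelError("odds ratios via basic parameters require a consistency fit")
    K = draws.n_treatments
    for t in (i, j):
        if not 1 <= t <= K:
            raise ModelError(f"unknown treatment index {t}")
    if i == j:
        return np.ones_like(draws.pooled("d[2]") if K > 1 else np.ones(1))
    di = 0.0 if i == 1 else draws.pooled(f"d[{i}]")
    dj = 0.0 if j == 1 else draws.pooled(f"d[{j}]")
    return np.exp(dj - di)
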