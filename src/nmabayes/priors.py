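"""Prior configuration for the binomial-logit NMA models.

Two heterogeneity-prior families are supported for the random-effects
between-study standard deviation sigma:

* ``uniform(0, U)`` on sigma itself — the conventional vague choice,
  default U = 2 (log odds-ratio scale);
* ``lognormal(m, s^2)`` on the *variance* sigma^2 — informative priors in
  the style of Turner et al. (2012), "Predicting the extent of
  heterogeneity in meta-analysis, using empirical data from the Cochrane
  Database of Systematic Reviews", Int J Epidemiol 41(3):818-827,
  doi:10.1093/ije/dys041, keyed by outcome type and comparison type.

Baselines (per-study log odds mu_i) and basic parameters (log odds ratios
d_k) always carry vague normal priors, by default Normal(0, 100^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class HeterogeneityPrior:
    """Prior for the between-study sd sigma.

    ``kind`` is ``"uniform"`` (uniform on sigma over ``(0, upper)``) or
    ``"lognormal"`` (lognormal on sigma^2 with log-mean ``m`` and log-sd
    ``s``; the implied density on sigma carries the 2*sigma Jacobian).
    """

    kind: str = "uniform"
    upper: float = 2.0
    m: float = 0.0
    s: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "lognormal"):
            raise ValueError(f"unknown heterogeneity prior kind {self.kind!r}")
        if self.kind == "uniform" and self.upper <= 0:
            raise ValueError("uniform upper bound must be positive")
        if self.kind == "lognormal" and self.s <= 0:
            raise ValueError("lognormal s must be positive")

    def log_density_sigma(self, sigma: float) -> float:
        """Log prior density evaluated on the sigma scale."""
        if sigma <= 0:
            return -math.inf
        if self.kind == "uniform":
            if sigma >= self.upper:
                return -math.inf
            return -math.log(self.upper)
        # lognormal on sigma^2, transformed to sigma: p(sigma) = LN(sigma^2) * 2 sigma
        z = (math.log(sigma**2) - self.m) / self.s
        log_ln = -math.log(sigma**2) - math.log(self.s) \
            - 0.5 * math.log(2 * math.pi) - 0.5 * z * z
        return log_ln + math.log(2 * sigma)

    def support(self) -> tuple[float, float]:
        return (0.0, self.upper if self.kind == "uniform" else math.inf)

    def central_half(self) -> tuple[float, float]:
        """Interquartile-style central half of the prior on sigma (used to
        randomize chain initial values)."""
        if self.kind == "uniform":
            return (0.25 * self.upper, 0.75 * self.upper)
        q25 = math.exp(self.m - 0.6744897501960817 * self.s)
        q75 = math.exp(self.m + 0.6744897501960817 * self.s)
        return (math.sqrt(q25), math.sqrt(q75))


@dataclass(frozen=True)
class PriorConfig:
    """Priors of one model fit.

    baseline_sd / effect_sd are the standard deviations of the zero-mean
    normal priors on per-study baselines mu_i and basic parameters d_k
    (default 100, i.e. variance 1e4).
    """

    baseline_sd: float = 100.0
    effect_sd: float = 100.0
    heterogeneity: HeterogeneityPrior = field(default_factory=HeterogeneityPrior)

    def __post_init__(self) -> None:
        if self.baseline_sd <= 0 or self.effect_sd <= 0:
            raise ValueError("prior standard deviations must be positive")


# ---------------------------------------------------------------------------
# Informative heterogeneity priors, Turner et al. 2012 (doi:10.1093/ije/dys041).
# Lognormal predictive distributions for the between-study variance tau^2 of
# log odds ratios, keyed by (outcome category, comparison category).  The
# entries below are transcriptions of the most commonly quoted rows of that
# publication's predictive table for pharmacological-vs-placebo/control
# comparisons; the table is deliberately an editable plain dict so users can
# add or amend rows against the primary source for their own setting.
TURNER_PRIORS: dict[tuple[str, str], HeterogeneityPrior] = {
    ("all-cause mortality", "pharmacological vs placebo"): HeterogeneityPrior(
        kind="lognormal", m=-4.06, s=1.45
    ),
    ("semi-objective", "pharmacological vs placebo"): HeterogeneityPrior(
        kind="lognormal", m=-3.02, s=1.85
    ),
    ("subjective", "pharmacological vs placebo"): HeterogeneityPrior(
        kind="lognormal", m=-2.13, s=1.58
    ),
}


def turner_prior(outcome_category: str, comparison_category: str) -> HeterogeneityPrior:
    """Look up an informative heterogeneity prior by category pair."""
    key = (outcome_category.strip().lower(), comparison_category.strip().lower())
    try:
        return TURNER_PRIORS[key]
    except KeyError:
        known = sorted(TURNER_PRIORS)
        raise KeyError(
            f"no informative prior for {key!r}; known category pairs: {known}"
        ) from None


def vague_priors(uniform_upper: float = 2.0) -> PriorConfig:
    """The conventional vague configuration: Normal(0, 100^2) on mu and d,
    Uniform(0, uniform_upper) on sigma."""
    return PriorConfig(heterogeneity=HeterogeneityPrior(kind="uniform",
                                                        upper=uniform_upper))


def informative_priors(outcome_category: str, comparison_category: str) -> PriorConfig:
    """Vague normals on mu and d with a Turner-style lognormal variance prior."""
    return PriorConfig(heterogeneity=turner_prior(outcome_category,
                                                  comparison_category))
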