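"""Adaptive random-walk Metropolis-within-Gibbs sampling of the NMA posterior.

Each scalar parameter block (every study baseline mu_i, every effect
parameter d, every trial-specific delta_ik, the between-study sd sigma)
is updated in turn with a Gaussian random-walk proposal.  Per-block step
sizes adapt toward an acceptance rate of ~0.44 during burn-in and are
frozen afterwards, so the post-burn-in kernel is a fixed Markov kernel
and retained draws target the exact posterior.

Multiple independent chains start from randomized initial values (uniform
draws over configurable ranges, the standard device for convergence
checking); everything is deterministic given ``(base_seed, chain)``.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import ModelError
from .data import ModelArrays
from .models import (
    ModelSpec,
    ParameterState,
    effect_prior_means,
    log_posterior,
    n_effect_parameters,
    ume_parameterize,
)

_ADAPT_INTERVAL = 100
_TARGET_ACCEPT = 0.44
_MAX_INIT_RETRIES = 50
_CLAMP = 500.0

DEFAULT_MONITORS = ("mu", "d", "sigma", "p")


@dataclass(frozen=True)
class MCMCSettings:
    """Chain-count, iteration and initialization settings.

    ``n_sample`` counts post-burn-in iterations; the retained length per
    chain is ``n_sample // thin``.  Initial values are drawn uniformly:
    baselines (log odds) from ``init_range_logodds``, effect parameters
    (log odds ratios) from ``init_range_logor``, sigma from the central
    half of its prior support, while the deltas start at their
    conditional means.
    """

    n_chains: int = 3
    n_burnin: int = 20_000
    n_sample: int = 40_000
    thin: int = 1
    init_range_logodds: tuple[float, float] = (-2.0, 2.0)
    init_range_logor: tuple[float, float] = (-2.0, 2.0)
    base_seed: int = 0
    monitors: tuple[str, ...] = DEFAULT_MONITORS

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ModelError("at least 2 chains are required for convergence checks")
        if self.thin < 1 or self.n_sample < 1 or self.n_burnin < 0:
            raise ModelError("invalid iteration settings")
        for lo, hi in (self.init_range_logodds, self.init_range_logor):
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ModelError("initial-value ranges must be finite, non-degenerate")
        bad = set(self.monitors) - {"mu", "d", "sigma", "delta", "p"}
        if bad:
            raise ModelError(f"unknown monitors: {sorted(bad)}")

    @property
    def n_kept(self) -> int:
        return self.n_sample // self.thin


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained draws of all monitored quantities, one matrix per chain.

    Columns are named (``mu[i]``, ``d[k]`` or ``d[b:j]`` for UME,
    ``sigma``, ``delta[i,k]``, ``p[j]`` for the j-th data point in
    study-major arm order).  ``arm_labels`` maps data points back to
    (study, treatment).
    """

    names: tuple[str, ...]
    chains: tuple[np.ndarray, ...]
    spec: ModelSpec
    settings: MCMCSettings
    arm_labels: tuple[tuple[str, str], ...]
    treatment_labels: tuple[str, ...]
    acceptance: tuple[dict[str, float], ...] = field(repr=False, default=())
    step_sizes: tuple[dict[str, float], ...] = field(repr=False, default=())
    corrected_data: bool = False

    @property
    def n_treatments(self) -> int:
        return len(self.treatment_labels)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_kept(self) -> int:
        return self.chains[0].shape[0]

    def has(self, name: str) -> bool:
        return name in self.names

    def get(self, name: str) -> list[np.ndarray]:
        """Per-chain 1-D arrays for one monitored quantity."""
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(f"quantity {name!r} was not monitored") from None
        return [c[:, j] for c in self.chains]

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated."""
        return np.concatenate(self.get(name))

    def parameters(self, prefix: str | None = None) -> list[str]:
        if prefix is None:
            return list(self.names)
        return [n for n in self.names if n.startswith(prefix)]

    def fitted_probability_names(self) -> list[str]:
        return self.parameters("p[")

    def to_table(self, path) -> None:
        """Plain-text draws table (chain, iteration, parameter, value)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("chain,iteration,parameter,value\n")
            for c, mat in enumerate(self.chains):
                for j, name in enumerate(self.names):
                    col = mat[:, j]
                    for it, v in enumerate(col):
                        fh.write(f"{c},{it},{name},{v!r}\n")


def _expit(x: float) -> float:
    x = max(-_CLAMP, min(_CLAMP, x))
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def effect_parameter_names(spec: ModelSpec, arrays: ModelArrays) -> list[str]:
    if spec.is_ume:
        return [f"d[{b}:{o}]" for b, o in ume_parameterize(arrays)]
    return [f"d[{k}]" for k in range(2, arrays.n_treatments + 1)]


def _chain_rng(settings: MCMCSettings, chain: int) -> random.Random:
    return random.Random(f"nmabayes:{settings.base_seed}:{chain}")


def initialize(
    spec: ModelSpec,
    arrays: ModelArrays,
    settings: MCMCSettings,
    chain: int,
    rng: random.Random | None = None,
) -> ParameterState:
    """Randomized initial state, deterministic given (base_seed, chain)."""
    if chain >= settings.n_chains:
        raise ModelError(f"chain {chain} out of range")
    if rng is None:
        rng = _chain_rng(settings, chain)
    lo, hi = settings.init_range_logodds
    mu = tuple(rng.uniform(lo, hi) for _ in range(arrays.n_studies))
    lo, hi = settings.init_range_logor
    d = tuple(rng.uniform(lo, hi) for _ in range(n_effect_parameters(spec, arrays)))
    delta = None
    sigma = None
    if spec.is_random:
        means = effect_prior_means(d, spec, arrays)
        delta = tuple(tuple(m) for m in means)  # conditional means
        slo, shi = spec.priors.heterogeneity.central_half()
        sigma = rng.uniform(slo, shi)
    return ParameterState(mu=mu, d=d, delta=delta, sigma=sigma)


def run_chain(
    spec: ModelSpec,
    arrays: ModelArrays,
    settings: MCMCSettings,
    chain: int,
) -> tuple[np.ndarray, tuple[str, ...], dict[str, float], dict[str, float]]:
    """Run one chain; returns (draws matrix, column names, acceptance, steps)."""
    rng = _chain_rng(settings, chain)
    state = None
    for _ in range(_MAX_INIT_RETRIES):
        cand = initialize(spec, arrays, settings, chain, rng=rng)
        if math.isfinite(log_posterior(arrays, cand, spec)):
            state = cand
            break
    if state is None:
        raise ModelError("could not find a finite-posterior initial state")

    S = arrays.n_studies
    na = arrays.na
    t = arrays.t
    r = arrays.r
    n = arrays.n
    random_effects = spec.is_random
    ume = spec.is_ume
    K = arrays.n_treatments
    Pd = n_effect_parameters(spec, arrays)

    logC = [
        [
            math.lgamma(n[i][k] + 1)
            - math.lgamma(r[i][k] + 1)
            - math.lgamma(n[i][k] - r[i][k] + 1)
            for k in range(na[i])
        ]
        for i in range(S)
    ]

    # mutable state
    mu = list(state.mu)
    d = list(state.d)
    sigma = state.sigma
    delta = [list(dd) for dd in state.delta] if random_effects else None

    if ume:
        comp = ume_parameterize(arrays)
        comp_index = {pair: c for c, pair in enumerate(comp)}
        comp_of = [
            [comp_index[(t[i][0], t[i][k])] for k in range(1, na[i])]
            for i in range(S)
        ]
        affected = [
            [i for i in range(S) if j in comp_of[i]] for j in range(Pd)
        ]
    else:
        affected = [
            [i for i in range(S) if (j + 2) in t[i]] for j in range(Pd)
        ]

    def means_of(i: int, dvec) -> list[float]:
        if ume:
            return [dvec[c] for c in comp_of[i]]
        base = 0.0 if t[i][0] == 1 else dvec[t[i][0] - 2]
        return [
            (0.0 if t[i][k] == 1 else dvec[t[i][k] - 2]) - base
            for k in range(1, na[i])
        ]

    means = [means_of(i, d) for i in range(S)]

    exp_, log_, log1p_ = math.exp, math.log, math.log1p

    def arm_ll(i: int, k: int, x: float) -> float:
        if x > _CLAMP:
            x = _CLAMP
        elif x < -_CLAMP:
            x = -_CLAMP
        if x >= 0:
            lp = -log1p_(exp_(-x))
            l1mp = -x + lp
        else:
            lp = x - log1p_(exp_(x))
            l1mp = lp - x
        return logC[i][k] + r[i][k] * lp + (n[i][k] - r[i][k]) * l1mp

    def study_ll(i: int, mu_i: float, deltas_i) -> float:
        tot = arm_ll(i, 0, mu_i)
        for k in range(1, na[i]):
            tot += arm_ll(i, k, mu_i + deltas_i[k - 1])
        return tot

    log_2pi = math.log(2 * math.pi)

    def re_dens(i: int, deltas_i, means_i, s2: float) -> float:
        m = na[i] - 1
        sx = 0.0
        sq = 0.0
        for j in range(m):
            v = deltas_i[j] - means_i[j]
            sx += v
            sq += v * v
        q = (2.0 / s2) * (sq - sx * sx / (m + 1))
        return -0.5 * (m * log_2pi + m * log_(s2 / 2.0) + log_(m + 1) + q)

    prior = spec.priors
    inv2_vmu = 0.5 / (prior.baseline_sd**2)
    inv2_vd = 0.5 / (prior.effect_sd**2)
    het = prior.heterogeneity
    sigma_support = het.support()

    if random_effects:
        # translation-move coefficients: how the delta prior mean of arm
        # (i, k) responds to a unit change of effect parameter j
        if ume:
            coef = [
                [
                    (i, k, 1)
                    for i in affected[j]
                    for k in range(1, na[i])
                    if comp_of[i][k - 1] == j
                ]
                for j in range(Pd)
            ]
        else:
            coef = []
            for j in range(Pd):
                m_t = j + 2
                entries = []
                for i in affected[j]:
                    for k in range(1, na[i]):
                        c = (1 if t[i][k] == m_t else 0) - (
                            1 if t[i][0] == m_t else 0
                        )
                        if c:
                            entries.append((i, k, c))
                coef.append(entries)

    # block bookkeeping: names, step sizes, acceptance counters
    blocks: list[str] = [f"mu[{i + 1}]" for i in range(S)]
    effect_names = effect_parameter_names(spec, arrays)
    blocks += effect_names
    if random_effects:
        blocks += [
            f"delta[{i + 1},{k + 1}]" for i in range(S) for k in range(1, na[i])
        ]
        blocks.append("sigma")
        blocks += [f"shift:{name}" for name in effect_names]
        blocks.append("sigma_scale")
    step = dict.fromkeys(blocks, 0.5)
    acc_win = dict.fromkeys(blocks, 0)
    acc_post = dict.fromkeys(blocks, 0)

    n_burn, n_total = settings.n_burnin, settings.n_burnin + settings.n_sample
    thin, n_kept = settings.thin, settings.n_kept

    monitors = settings.monitors
    col_names: list[str] = []
    if "mu" in monitors:
        col_names += [f"mu[{i + 1}]" for i in range(S)]
    if "d" in monitors:
        col_names += effect_parameter_names(spec, arrays)
    if "sigma" in monitors and random_effects:
        col_names.append("sigma")
    if "delta" in monitors and random_effects:
        col_names += [
            f"delta[{i + 1},{k + 1}]" for i in range(S) for k in range(1, na[i])
        ]
    if "p" in monitors:
        col_names += [f"p[{j + 1}]" for j in range(arrays.n_datapoints)]
    out = np.empty((n_kept, len(col_names)))
    kept = 0

    gauss = rng.gauss
    unif = rng.random

    for it in range(n_total):
        adapting = it < n_burn

        # --- baselines
        for i in range(S):
            name = f"mu[{i + 1}]"
            cur = mu[i]
            dl = delta[i] if random_effects else means[i]
            cur_lp = study_ll(i, cur, dl) - inv2_vmu * cur * cur
            prop = cur + step[name] * gauss(0.0, 1.0)
            prop_lp = study_ll(i, prop, dl) - inv2_vmu * prop * prop
            if prop_lp - cur_lp > log_(unif() + 1e-300):
                mu[i] = prop
                acc_win[name] += 1
                if not adapting:
                    acc_post[name] += 1

        # --- trial-specific effects (random-effects models)
        if random_effects:
            s2 = sigma * sigma
            for i in range(S):
                if na[i] == 2:
                    name = f"delta[{i + 1},2]"
                    cur = delta[i][0]
                    mki = means[i][0]
                    cur_lp = arm_ll(i, 1, mu[i] + cur) - 0.5 * (cur - mki) ** 2 / s2
                    prop = cur + step[name] * gauss(0.0, 1.0)
                    prop_lp = arm_ll(i, 1, mu[i] + prop) - 0.5 * (prop - mki) ** 2 / s2
                    if prop_lp - cur_lp > log_(unif() + 1e-300):
                        delta[i][0] = prop
                        acc_win[name] += 1
                        if not adapting:
                            acc_post[name] += 1
                else:
                    for k in range(1, na[i]):
                        name = f"delta[{i + 1},{k + 1}]"
                        cur = delta[i][k - 1]
                        cur_lp = arm_ll(i, k, mu[i] + cur) + re_dens(
                            i, delta[i], means[i], s2
                        )
                        prop = cur + step[name] * gauss(0.0, 1.0)
                        delta[i][k - 1] = prop
                        prop_lp = arm_ll(i, k, mu[i] + prop) + re_dens(
                            i, delta[i], means[i], s2
                        )
                        if prop_lp - cur_lp > log_(unif() + 1e-300):
                            acc_win[name] += 1
                            if not adapting:
                                acc_post[name] += 1
                        else:
                            delta[i][k - 1] = cur

        # --- effect parameters
        for j in range(Pd):
            name = blocks[S + j]
            cur = d[j]
            prop = cur + step[name] * gauss(0.0, 1.0)
            d[j] = prop
            new_means = {i: means_of(i, d) for i in affected[j]}
            d[j] = cur
            if random_effects:
                s2 = sigma * sigma
                cur_lp = -inv2_vd * cur * cur
                prop_lp = -inv2_vd * prop * prop
                for i in affected[j]:
                    cur_lp += re_dens(i, delta[i], means[i], s2)
                    prop_lp += re_dens(i, delta[i], new_means[i], s2)
            else:
                cur_lp = -inv2_vd * cur * cur
                prop_lp = -inv2_vd * prop * prop
                for i in affected[j]:
                    cur_lp += study_ll(i, mu[i], means[i])
                    prop_lp += study_ll(i, mu[i], new_means[i])
            if prop_lp - cur_lp > log_(unif() + 1e-300):
                d[j] = prop
                for i, m_new in new_means.items():
                    means[i] = m_new
                acc_win[name] += 1
                if not adapting:
                    acc_post[name] += 1

        # --- between-study sd
        if random_effects:
            cur = sigma
            prop = cur + step["sigma"] * gauss(0.0, 1.0)
            if sigma_support[0] < prop < sigma_support[1]:
                cur_lp = het.log_density_sigma(cur)
                prop_lp = het.log_density_sigma(prop)
                cs2, ps2 = cur * cur, prop * prop
                for i in range(S):
                    cur_lp += re_dens(i, delta[i], means[i], cs2)
                    prop_lp += re_dens(i, delta[i], means[i], ps2)
                if prop_lp - cur_lp > log_(unif() + 1e-300):
                    sigma = prop
                    acc_win["sigma"] += 1
                    if not adapting:
                        acc_post["sigma"] += 1

        # --- joint translation moves: (d_j, affected deltas) shift together,
        # leaving the random-effects residuals (hence their density) unchanged
        if random_effects:
            for j in range(Pd):
                name = f"shift:{effect_names[j]}"
                eps = step[name] * gauss(0.0, 1.0)
                cur = d[j]
                prop = cur + eps
                dlp = inv2_vd * (cur * cur - prop * prop)
                for i, k, c in coef[j]:
                    x = mu[i] + delta[i][k - 1]
                    dlp += arm_ll(i, k, x + c * eps) - arm_ll(i, k, x)
                if dlp > log_(unif() + 1e-300):
                    d[j] = prop
                    for i, k, c in coef[j]:
                        delta[i][k - 1] += c * eps
                    for i in affected[j]:
                        means[i] = means_of(i, d)
                    acc_win[name] += 1
                    if not adapting:
                        acc_post[name] += 1

            # --- joint rescaling move: sigma and all residuals scale by e^eps;
            # the z-scores are invariant, so only the likelihood of the
            # non-baseline arms, the sigma prior and a log(scale) Jacobian
            # term enter the acceptance ratio
            eps = step["sigma_scale"] * gauss(0.0, 1.0)
            scale = exp_(eps)
            prop_sigma = sigma * scale
            if sigma_support[0] < prop_sigma < sigma_support[1]:
                dlp = (
                    het.log_density_sigma(prop_sigma)
                    - het.log_density_sigma(sigma)
                    + eps
                )
                new_delta = [
                    [
                        means[i][k - 1]
                        + scale * (delta[i][k - 1] - means[i][k - 1])
                        for k in range(1, na[i])
                    ]
                    for i in range(S)
                ]
                for i in range(S):
                    for k in range(1, na[i]):
                        dlp += arm_ll(i, k, mu[i] + new_delta[i][k - 1]) - arm_ll(
                            i, k, mu[i] + delta[i][k - 1]
                        )
                if dlp > log_(unif() + 1e-300):
                    sigma = prop_sigma
                    delta = new_delta
                    acc_win["sigma_scale"] += 1
                    if not adapting:
                        acc_post["sigma_scale"] += 1

        # --- step-size adaptation (burn-in only)
        if adapting and (it + 1) % _ADAPT_INTERVAL == 0:
            for name in blocks:
                rate = acc_win[name] / _ADAPT_INTERVAL
                s = step[name] * exp_(rate - _TARGET_ACCEPT)
                step[name] = min(50.0, max(1e-5, s))
                acc_win[name] = 0
        elif not adapting and (it + 1 - n_burn) % _ADAPT_INTERVAL == 0:
            for name in blocks:
                acc_win[name] = 0

        # --- record
        if it >= n_burn and (it - n_burn) % thin == 0 and kept < n_kept:
            row: list[float] = []
            if "mu" in monitors:
                row += mu
            if "d" in monitors:
                row += d
            if "sigma" in monitors and random_effects:
                row.append(sigma)
            if "delta" in monitors and random_effects:
                for i in range(S):
                    row += delta[i]
            if "p" in monitors:
                for i in range(S):
                    row.append(_expit(mu[i]))
                    dl = delta[i] if random_effects else means[i]
                    for k in range(1, na[i]):
                        row.append(_expit(mu[i] + dl[k - 1]))
            out[kept] = row
            kept += 1

    n_post = settings.n_sample
    acceptance = {name: acc_post[name] / n_post for name in blocks}
    return out, tuple(col_names), acceptance, dict(step)


def run_mcmc(
    spec: ModelSpec, arrays: ModelArrays, settings: MCMCSettings | None = None
) -> PosteriorDraws:
    """Sample the posterior with ``settings.n_chains`` independent chains."""
    if settings is None:
        settings = MCMCSettings()
    chains = []
    names: tuple[str, ...] | None = None
    acc = []
    steps = []
    for c in range(settings.n_chains):
        mat, col_names, a, s = run_chain(spec, arrays, settings, c)
        chains.append(mat)
        names = col_names
        acc.append(a)
        steps.append(s)
    return PosteriorDraws(
        names=names,
        chains=tuple(chains),
        spec=spec,
        settings=settings,
        arm_labels=arrays.arm_labels,
        treatment_labels=arrays.treatment_labels,
        acceptance=tuple(acc),
        step_sizes=tuple(steps),
        corrected_data=arrays.corrected,
    )
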