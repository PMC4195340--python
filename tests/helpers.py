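"""Independent numerical oracles shared by sampler and acceptance tests."""

from __future__ import annotations

import math

import numpy as np

from nmabayes.models import binomial_logpmf


def grid_posterior_d2(
    arrays,
    prior_sd: float = 100.0,
    mu_range=(-6.0, 4.0),
    d_range=(-5.0, 6.0),
    n_mu: int = 801,
    n_d: int = 801,
):
    """Dense-grid posterior of the single basic parameter d_2 for a
    fixed-effect two-treatment model (any number of 2-arm studies).

    Given d_2 the studies factorize, so each per-study baseline mu_i is
    integrated out on its own 1-D grid: no MCMC anywhere.  Returns
    (d2_grid, normalized density on the grid).
    """
    mu = np.linspace(*mu_range, n_mu)
    d2 = np.linspace(*d_range, n_d)
    log_prior_mu = -0.5 * (mu / prior_sd) ** 2
    log_post = -0.5 * (d2 / prior_sd) ** 2
    for i in range(arrays.n_studies):
        assert arrays.na[i] == 2 and arrays.t[i] == (1, 2)
        ll1 = np.array(
            [binomial_logpmf(arrays.r[i][0], arrays.n[i][0], m) for m in mu]
        )
        ll2 = np.array(
            [
                [binomial_logpmf(arrays.r[i][1], arrays.n[i][1], m + d) for m in mu]
                for d in d2
            ]
        )
        integrand = ll2 + (ll1 + log_prior_mu)[None, :]
        m_max = integrand.max(axis=1, keepdims=True)
        log_post += m_max[:, 0] + np.log(
            np.trapezoid(np.exp(integrand - m_max), mu, axis=1)
        )
    log_post -= log_post.max()
    dens = np.exp(log_post)
    dens /= np.trapezoid(dens, d2)
    return d2, dens


def grid_mean(grid, dens) -> float:
    return float(np.trapezoid(grid * dens, grid))


def grid_quantile(grid, dens, q: float) -> float:
    cdf = np.concatenate(
        [[0.0], np.cumsum(np.diff(grid) * 0.5 * (dens[1:] + dens[:-1]))]
    )
    cdf /= cdf[-1]
    return float(np.interp(q, cdf, grid))


def batch_se(x: np.ndarray, n_batches: int = 50, stat=np.mean) -> float:
    """Batch-means standard error of an arbitrary statistic of the draws."""
    batch = len(x) // n_batches
    vals = [stat(x[i * batch : (i + 1) * batch]) for i in range(n_batches)]
    return float(np.std(vals, ddof=1) / math.sqrt(n_batches))
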