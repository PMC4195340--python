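"""Convergence diagnostics and model criticism.

Convergence: the potential scale reduction factor (Gelman–Rubin, assessed
per the Brooks–Gelman multi-chain recipe) and a Monte-Carlo-error rule of
thumb — the MC standard error of each monitored effect estimate and of
the between-study variance should be below 5% of its posterior sd.

Criticism: per-data-point residual deviance against the saturated model,
the deviance information criterion DIC = Dbar + pD, and the dev–dev
comparison of consistency and inconsistency fits used to localize
potential inconsistency in the network.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._exceptions import DiagnosticError
from .data import ModelArrays
from .sampler import PosteriorDraws

MC_ERROR_FRACTION = 0.05
DEFAULT_BATCHES = 50


def psrf(draws: PosteriorDraws | list[np.ndarray], parameter: str | None = None) -> float:
    """Potential scale reduction factor R-hat for one monitored quantity.

    R-hat = sqrt( ((n-1)/n * W + B/n) / W ) with W the mean within-chain
    variance and B/n the between-chain variance of the chain means; values
    close to 1 indicate approximate convergence.
    """
    chains = draws.get(parameter) if isinstance(draws, PosteriorDraws) else draws
    if len(chains) < 2:
        raise DiagnosticError("PSRF needs at least 2 chains")
    n = len(chains[0])
    if n < 4 or any(len(c) != n for c in chains):
        raise DiagnosticError("chains must share a retained length >= 4")
    w = float(np.mean([np.var(c, ddof=1) for c in chains]))
    if w == 0.0:
        raise DiagnosticError("zero within-chain variance: PSRF undefined")
    b_over_n = float(np.var([np.mean(c) for c in chains], ddof=1))
    return math.sqrt(((n - 1) / n * w + b_over_n) / w)


def mc_error(
    draws: PosteriorDraws | list[np.ndarray],
    parameter: str | None = None,
    n_batches: int = DEFAULT_BATCHES,
) -> float:
    """Batch-means Monte Carlo standard error of the posterior mean.

    Chains are concatenated and split into ``n_batches`` equal batches
    (any trailing remainder is dropped); the MC error is the sd of the
    batch means divided by sqrt(n_batches).
    """
    chains = draws.get(parameter) if isinstance(draws, PosteriorDraws) else draws
    pooled = np.concatenate(chains)
    if len(pooled) < 100:
        raise DiagnosticError("MC error needs at least 100 retained draws")
    batch = len(pooled) // n_batches
    trimmed = pooled[: batch * n_batches]
    batch_means = trimmed.reshape(n_batches, batch).mean(axis=1)
    return float(np.std(batch_means, ddof=1) / math.sqrt(n_batches))


@dataclass(frozen=True)
class ConvergenceReport:
    """Per-parameter PSRF, MC error and the 5%-of-sd rule outcome.

    ``overall_pass`` is True iff every monitored effect estimate (and the
    between-study sd, when present) satisfies MC error < 5% of its
    posterior sd.
    """

    parameters: tuple[str, ...]
    psrf: dict[str, float]
    mc_error: dict[str, float]
    posterior_sd: dict[str, float]
    mc_error_rule_pass: dict[str, bool]
    overall_pass: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "overall_pass": self.overall_pass,
                "parameters": [
                    {
                        "name": p,
                        "psrf": self.psrf[p],
                        "mc_error": self.mc_error[p],
                        "posterior_sd": self.posterior_sd[p],
                        "mc_error_rule_pass": self.mc_error_rule_pass[p],
                    }
                    for p in self.parameters
                ],
            },
            sort_keys=True,
        )


def convergence_report(
    draws: PosteriorDraws, parameters: list[str] | None = None
) -> ConvergenceReport:
    """Apply PSRF and the MC-error rule to the effect estimates.

    By default the checked set is every effect parameter plus sigma —
    the quantities whose simulation accuracy the 5% rule governs.
    """
    if parameters is None:
        parameters = draws.parameters("d[")
        if draws.has("sigma"):
            parameters = parameters + ["sigma"]
    rhat, err, sd, ok = {}, {}, {}, {}
    for p in parameters:
        rhat[p] = psrf(draws, p)
        err[p] = mc_error(draws, p)
        sd[p] = float(np.std(draws.pooled(p), ddof=1))
        ok[p] = err[p] < MC_ERROR_FRACTION * sd[p]
    return ConvergenceReport(
        parameters=tuple(parameters),
        psrf=rhat,
        mc_error=err,
        posterior_sd=sd,
        mc_error_rule_pass=ok,
        overall_pass=all(ok.values()),
    )


# ---------------------------------------------------------------------------
# residual deviance / DIC

def residual_deviance(arrays: ModelArrays, fitted_p: np.ndarray) -> np.ndarray:
    """Per-data-point binomial saturated deviance.

    dev = 2 [ r ln(r / rhat) + (n - r) ln((n - r)/(n - rhat)) ] with
    rhat = n p, using the 0 * ln(0) = 0 convention for boundary cells.
    """
    r = np.array([x for row in arrays.r for x in row], dtype=float)
    n = np.array([x for row in arrays.n for x in row], dtype=float)
    p = np.asarray(fitted_p, dtype=float)
    if p.shape != r.shape:
        raise DiagnosticError("fitted_p length does not match the data points")
    if np.any(p <= 0) or np.any(p >= 1):
        raise DiagnosticError("fitted probabilities must lie strictly in (0, 1)")
    rhat = n * p
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(r > 0, r * np.log(r / rhat), 0.0)
        t2 = np.where(n - r > 0, (n - r) * np.log((n - r) / (n - rhat)), 0.0)
    return 2.0 * (t1 + t2)


@dataclass(frozen=True)
class FitStatistics:
    """Residual-deviance fit summary: DIC = Dbar + pD, pD = Dbar - Dhat."""

    dbar: float
    pd: float
    dic: float
    per_point_dbar: tuple[float, ...]
    arm_labels: tuple[tuple[str, str], ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "Dbar": self.dbar,
                "pD": self.pd,
                "DIC": self.dic,
                "points": [
                    {"study": s, "treatment": t, "dbar": v}
                    for (s, t), v in zip(self.arm_labels, self.per_point_dbar)
                ],
            },
            sort_keys=True,
        )


def dic(draws: PosteriorDraws, arrays: ModelArrays) -> FitStatistics:
    """Deviance information criterion from monitored fitted probabilities.

    Dbar is the posterior mean of the total residual deviance, Dhat the
    deviance at the posterior means of the per-arm probabilities (the
    convention for arm-based binomial models), pD = Dbar - Dhat.
    """
    p_names = draws.fitted_probability_names()
    if not p_names:
        raise DiagnosticError(
            "DIC requires monitored fitted probabilities (monitor 'p')"
        )
    if arrays.corrected:
        warnings.warn(
            "fit statistics computed on continuity-corrected data: zero-cell "
            "adjustments can make model fit look artificially better",
            stacklevel=2,
        )
    pmat = np.column_stack([draws.pooled(name) for name in p_names])
    r = np.array([x for row in arrays.r for x in row], dtype=float)
    n = np.array([x for row in arrays.n for x in row], dtype=float)
    rhat = n * pmat  # (draws, points), broadcast over draws
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(r > 0, r * np.log(r / rhat), 0.0)
        t2 = np.where(n - r > 0, (n - r) * np.log((n - r) / (n - rhat)), 0.0)
    per_point = (2.0 * (t1 + t2)).mean(axis=0)
    dbar = float(per_point.sum())
    dhat = float(residual_deviance(arrays, pmat.mean(axis=0)).sum())
    pd_ = dbar - dhat
    return FitStatistics(
        dbar=dbar,
        pd=pd_,
        dic=dbar + pd_,
        per_point_dbar=tuple(float(v) for v in per_point),
        arm_labels=arrays.arm_labels,
    )


def devdev_table(
    cons_fit: FitStatistics,
    incons_fit: FitStatistics,
    flag_margin: float = 0.5,
) -> list[dict]:
    """Pair per-point posterior mean deviances of consistency vs inconsistency fits.

    One labeled record per data point, so any point in the scatter can be
    identified as a specific (study, arm).  Points where the consistency
    deviance exceeds the inconsistency deviance by more than
    ``flag_margin`` are flagged as potential inconsistency.
    """
    if cons_fit.arm_labels != incons_fit.arm_labels:
        raise DiagnosticError("fits cover different data-point sets")
    rows = []
    for (study, treatment), dc, di in zip(
        cons_fit.arm_labels, cons_fit.per_point_dbar, incons_fit.per_point_dbar
    ):
        rows.append(
            {
                "study": study,
                "treatment": treatment,
                "dev_consistency": float(dc),
                "dev_inconsistency": float(di),
                "flag": bool(dc - di > flag_margin),
            }
        )
    return rows


def write_devdev_csv(rows: list[dict], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=["study", "treatment", "dev_consistency",
                        "dev_inconsistency", "flag"],
        )
        writer.writeheader()
        writer.writerows(rows)
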