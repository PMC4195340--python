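"""Scikit-learn-style front end: the :class:`NetworkMetaAnalysis` estimator.

The estimator wraps the whole workflow — validation, optional zero-cell
correction, MCMC sampling, convergence checking and reporting — behind
the familiar ``fit()`` + fitted-attribute surface, so model variants can
be cloned, parametrized and compared with standard scikit-learn tooling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._exceptions import DataError
from .data import (
    NMADataset,
    apply_continuity_correction,
    build_network,
    dataset_from_rows,
    prepare_model_arrays,
    summarize,
)
from .diagnostics import convergence_report, dic
from .models import ModelSpec, consistency_or
from .priors import informative_priors, vague_priors
from .report import (
    PosteriorSummary,
    league_table,
    rank_probabilities,
    summarize_posterior,
)
from .sampler import MCMCSettings, run_mcmc


class NetworkMetaAnalysis(BaseEstimator):
    """Bayesian network meta-analysis of arm-level binomial data.

    Parameters
    ----------
    effect : "random" | "fixed"
        Fixed-effect or random-effects (between-study heterogeneity) model.
    framework : "consistency" | "inconsistency"
        Consistency (basic-parameter) model or the unrelated-mean-effects
        inconsistency model.
    heterogeneity : "vague" | tuple(outcome_category, comparison_category)
        Vague Uniform(0, ``sigma_upper``) prior on the between-study sd,
        or an informative lognormal variance prior selected by category
        pair (random effects only).
    direction : "bad" | "good"
        Whether the modelled event harms ("bad", e.g. death) or benefits
        the patient; affects ranking/league ordering only.
    correct_zeros : bool
        Apply the sample-size-adjusted continuity correction (centered
        around 0.5) to studies with zero or all-event cells.
    reference : str or None
        Reference treatment label; default: the treatment present in the
        most studies.
    n_chains, n_burnin, n_sample, thin, seed, init_range_logodds,
    init_range_logor
        MCMC settings (see :class:`~nmabayes.sampler.MCMCSettings`).

    Attributes
    ----------
    dataset_ : NMADataset           validated (possibly corrected) data
    network_ : EvidenceNetwork      evidence-network structure
    draws_ : PosteriorDraws         retained posterior draws
    convergence_ : ConvergenceReport
    fit_stats_ : FitStatistics      Dbar / pD / DIC
    summary_ : pandas.DataFrame     per-parameter posterior summaries
    sucra_ : dict[str, float]       SUCRA per treatment (consistency only)
    rank_table_ : RankTable
    league_table_ : LeagueTable
    """

    def __init__(
        self,
        effect: str = "random",
        framework: str = "consistency",
        heterogeneity="vague",
        direction: str = "bad",
        correct_zeros: bool = False,
        reference: str | None = None,
        sigma_upper: float = 2.0,
        n_chains: int = 3,
        n_burnin: int = 20_000,
        n_sample: int = 40_000,
        thin: int = 1,
        seed: int = 0,
        init_range_logodds: tuple[float, float] = (-2.0, 2.0),
        init_range_logor: tuple[float, float] = (-2.0, 2.0),
    ):
        self.effect = effect
        self.framework = framework
        self.heterogeneity = heterogeneity
        self.direction = direction
        self.correct_zeros = correct_zeros
        self.reference = reference
        self.sigma_upper = sigma_upper
        self.n_chains = n_chains
        self.n_burnin = n_burnin
        self.n_sample = n_sample
        self.thin = thin
        self.seed = seed
        self.init_range_logodds = init_range_logodds
        self.init_range_logor = init_range_logor

    # -- assembly -----------------------------------------------------------

    def _make_spec(self) -> ModelSpec:
        if self.heterogeneity == "vague":
            priors = vague_priors(self.sigma_upper)
        elif isinstance(self.heterogeneity, (tuple, list)) and len(self.heterogeneity) == 2:
            priors = informative_priors(*self.heterogeneity)
        else:
            raise DataError(
                "heterogeneity must be 'vague' or an (outcome, comparison) "
                "category pair"
            )
        return ModelSpec(
            effect=self.effect,
            framework=self.framework,
            priors=priors,
            direction=self.direction,
        )

    def _make_settings(self) -> MCMCSettings:
        return MCMCSettings(
            n_chains=self.n_chains,
            n_burnin=self.n_burnin,
            n_sample=self.n_sample,
            thin=self.thin,
            init_range_logodds=tuple(self.init_range_logodds),
            init_range_logor=tuple(self.init_range_logor),
            base_seed=self.seed,
        )

    def _coerce_dataset(self, X) -> NMADataset:
        if isinstance(X, NMADataset):
            ds = X
            if self.reference is not None:
                from .data import set_reference

                ds = set_reference(ds, ds.treatment_index(self.reference))
            return ds
        if isinstance(X, pd.DataFrame):
            needed = {"study", "treatment", "events", "n"}
            if not needed.issubset(X.columns):
                raise DataError(
                    f"DataFrame input needs columns {sorted(needed)}"
                )
            rows = [
                (str(r.study), str(r.treatment), float(r.events), float(r.n))
                for r in X.itertuples()
            ]
            return dataset_from_rows(rows, reference=self.reference)
        raise DataError(
            f"cannot interpret {type(X).__name__} as an NMA dataset; pass an "
            "NMADataset or a long-format DataFrame"
        )

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y=None):
        """Validate data, sample the posterior and build all summaries."""
        ds = self._coerce_dataset(X)
        if self.correct_zeros:
            ds = apply_continuity_correction(ds)
        spec = self._make_spec()
        self.dataset_ = ds
        self.data_summary_ = summarize(ds)
        self.network_ = build_network(ds)
        self.arrays_ = prepare_model_arrays(ds)
        self.spec_ = spec
        self.draws_ = run_mcmc(spec, self.arrays_, self._make_settings())
        self.convergence_ = convergence_report(self.draws_)
        self.fit_stats_ = dic(self.draws_, self.arrays_)
        rows = []
        for name in self.draws_.parameters("d[") + (
            ["sigma"] if self.draws_.has("sigma") else []
        ):
            s = summarize_posterior(self.draws_, name)
            rows.append(
                {
                    "parameter": name,
                    "median": s.median,
                    "lower": s.lower,
                    "upper": s.upper,
                    "mean": s.mean,
                    "sd": s.sd,
                }
            )
        self.summary_ = pd.DataFrame(rows).set_index("parameter")
        if spec.framework == "consistency":
            self.rank_table_ = rank_probabilities(self.draws_)
            self.sucra_ = dict(
                zip(self.rank_table_.treatments, self.rank_table_.sucra)
            )
            self.league_table_ = league_table(self.draws_, self.rank_table_)
        return self

    def odds_ratio(self, treatment, versus) -> PosteriorSummary:
        """Posterior summary of OR(``treatment`` vs ``versus``); labels or
        1-based indices accepted (consistency fits only)."""
        self._check_fitted()
        ds = self.dataset_
        t = treatment if isinstance(treatment, int) else ds.treatment_index(treatment)
        v = versus if isinstance(versus, int) else ds.treatment_index(versus)
        draws = consistency_or(self.draws_, v, t)
        label = f"OR({ds.label(t)} vs {ds.label(v)})"
        return summarize_posterior(draws, label)

    def or_draws(self, treatment, versus) -> np.ndarray:
        """Per-draw odds ratios of ``treatment`` vs ``versus``."""
        self._check_fitted()
        ds = self.dataset_
        t = treatment if isinstance(treatment, int) else ds.treatment_index(treatment)
        v = versus if isinstance(versus, int) else ds.treatment_index(versus)
        return consistency_or(self.draws_, v, t)

    def _check_fitted(self) -> None:
        if not hasattr(self, "draws_"):
            raise DataError("this NetworkMetaAnalysis instance is not fitted yet")
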