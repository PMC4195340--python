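"""Likelihood, priors, multi-arm conditionals and parameterizations."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import integrate, stats

import nmabayes as nb
from nmabayes.data import ModelArrays
from nmabayes.models import binomial_logpmf, effect_prior_means
from nmabayes.priors import HeterogeneityPrior


def single_arm_arrays(r, n):
    return ModelArrays(t=((1,),), r=((float(r),),), n=((float(n),),),
                       na=(1,), study_labels=("S",), treatment_labels=("A",))


FE = nb.ModelSpec(effect="fixed")
RE = nb.ModelSpec(effect="random")


class TestLikelihood:
    def test_half_probability_closed_form(self):
        arrays = single_arm_arrays(1, 2)
        state = nb.ParameterState(mu=(0.0,), d=())
        assert nb.log_likelihood(arrays, state, FE) == pytest.approx(math.log(0.5))

    def test_boundary_guarded_finite(self):
        arrays = single_arm_arrays(3, 10)
        state = nb.ParameterState(mu=(-1e9,), d=())  # p -> 0 with r > 0
        ll = nb.log_likelihood(arrays, state, FE)
        assert math.isfinite(ll) and ll < -1000

    def test_independent_binomial_sum_oracle(self, heart_arrays):
        state = nb.ParameterState(
            mu=(0.0,) * heart_arrays.n_studies, d=(0.0,) * 4
        )
        expected = sum(
            stats.binom.logpmf(r, n, 0.5)
            for rr, nn in zip(heart_arrays.r, heart_arrays.n)
            for r, n in zip(rr, nn)
        )
        got = nb.log_likelihood(heart_arrays, state, FE)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_fractional_counts_log_gamma_extension(self):
        # corrected cell 0.5/30: the continuous extension matches the
        # explicit lgamma formula
        got = binomial_logpmf(0.5, 30.0, 0.0)
        expected = (
            math.lgamma(31) - math.lgamma(1.5) - math.lgamma(30.5)
            + 30 * math.log(0.5)
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch_rejected(self, heart_arrays):
        state = nb.ParameterState(mu=(0.0,), d=(0.0,) * 4)
        with pytest.raises(nb.ModelError):
            nb.log_likelihood(heart_arrays, state, FE)


class TestConditionalDelta:
    @pytest.fixture()
    def three_arm(self):
        arrays = ModelArrays(
            t=((1, 2, 3),), r=((1.0, 2.0, 3.0),), n=((10.0,) * 3,),
            na=(3,), study_labels=("S",), treatment_labels=("A", "B", "C"),
        )
        state = nb.ParameterState(
            mu=(0.0,), d=(0.4, 0.9), delta=((0.4, 0.9),), sigma=1.0
        )
        return arrays, state

    def test_two_arm_reduces_to_unconditional(self, three_arm):
        arrays, state = three_arm
        mean, var = nb.conditional_delta(state, RE, arrays, 0, 2)
        assert var == pytest.approx(state.sigma**2)
        assert mean == pytest.approx(0.4)

    def test_three_arm_conditional_variance(self, three_arm):
        arrays, state = three_arm
        _, var = nb.conditional_delta(state, RE, arrays, 0, 3)
        assert var == pytest.approx(0.75)

    def test_mean_reduces_when_earlier_delta_at_prior_mean(self, three_arm):
        arrays, state = three_arm
        mean, _ = nb.conditional_delta(state, RE, arrays, 0, 3)
        assert mean == pytest.approx(0.9)  # d_C - d_A, correction vanishes

    def test_matches_multivariate_normal_conditional(self):
        # independent oracle: condition the explicit 2-d normal numerically
        sigma = 0.7
        cov = sigma**2 / 2 * (np.eye(2) + np.ones((2, 2)))
        arrays = ModelArrays(
            t=((1, 2, 3),), r=((1.0, 2.0, 3.0),), n=((10.0,) * 3,),
            na=(3,), study_labels=("S",), treatment_labels=("A", "B", "C"),
        )
        state = nb.ParameterState(
            mu=(0.0,), d=(0.2, -0.3), delta=((0.9, 0.0),), sigma=sigma
        )
        mean, var = nb.conditional_delta(state, RE, arrays, 0, 3)
        m = np.array([0.2, -0.3])  # d_B - d_A, d_C - d_A
        cond_mean = m[1] + cov[1, 0] / cov[0, 0] * (0.9 - m[0])
        cond_var = cov[1, 1] - cov[1, 0] ** 2 / cov[0, 0]
        assert mean == pytest.approx(cond_mean)
        assert var == pytest.approx(cond_var)

    def test_baseline_arm_rejected(self, three_arm):
        arrays, state = three_arm
        with pytest.raises(nb.ModelError):
            nb.conditional_delta(state, RE, arrays, 0, 1)


class TestPriors:
    def test_sigma_outside_uniform_support(self):
        state = nb.ParameterState(mu=(0.0,), d=(0.0,), delta=((0.0,),), sigma=2.5)
        assert nb.log_prior(state, RE) == -math.inf

    def test_vague_normal_sum_at_zero(self, heart_arrays):
        state = nb.ParameterState(mu=(0.0,) * 12, d=(0.0,) * 4)
        expected = (12 + 4) * stats.norm.logpdf(0.0, scale=100.0)
        assert nb.log_prior(state, FE) == pytest.approx(expected)

    def test_lognormal_sigma_density_integrates_to_one(self):
        prior = HeterogeneityPrior(kind="lognormal", m=-2.0, s=1.5)
        total, _ = integrate.quad(
            lambda s: math.exp(prior.log_density_sigma(s)), 1e-9, 50
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_lognormal_peak_region(self):
        prior = HeterogeneityPrior(kind="lognormal", m=-2.0, s=1.0)
        near_mode = prior.log_density_sigma(math.exp(-1.0))  # sigma^2 = e^m
        assert near_mode > prior.log_density_sigma(2.0)
        assert near_mode > prior.log_density_sigma(0.01)

    def test_posterior_finite_interior_infinite_at_boundary(self, heart_arrays):
        interior = nb.ParameterState(
            mu=(0.1,) * 12, d=(0.2, -0.1, 0.0, 0.3),
            delta=tuple((0.0,) * (na - 1) for na in heart_arrays.na),
            sigma=0.5,
        )
        assert math.isfinite(nb.log_posterior(heart_arrays, interior, RE))
        boundary = nb.ParameterState(
            mu=interior.mu, d=interior.d, delta=interior.delta, sigma=2.0
        )
        assert nb.log_posterior(heart_arrays, boundary, RE) == -math.inf


class TestUMEParameterization:
    def test_bundled_comparisons(self, heart):
        assert nb.ume_parameterize(heart) == (
            (1, 2), (1, 3), (1, 4), (1, 5), (3, 4), (3, 5)
        )

    def test_single_study_single_parameter(self, toy2):
        assert len(nb.ume_parameterize(toy2)) == 1

    def test_repeated_comparison_shares_parameter(self, toy2):
        rows = [("S1", "A", 5, 20), ("S1", "B", 10, 20),
                ("S2", "A", 3, 15), ("S2", "B", 8, 15),
                ("S3", "A", 4, 12), ("S3", "B", 6, 12)]
        ds = nb.dataset_from_rows(rows, treatment_order=["A", "B"])
        assert nb.ume_parameterize(ds) == nb.ume_parameterize(toy2)

    def test_ume_prior_means_are_per_comparison(self, heart_arrays):
        spec = nb.ModelSpec(effect="fixed", framework="inconsistency")
        d = tuple(float(i) for i in range(6))
        means = effect_prior_means(d, spec, heart_arrays)
        i = heart_arrays.study_labels.index("COMPANION")  # arms A, B, D
        assert means[i] == [0.0, 2.0]  # comparisons (1,2) and (1,4)


class TestConsistencyOR:
    def test_identity_and_reciprocity(self, heart_draws):
        assert np.allclose(nb.consistency_or(heart_draws, 2, 2), 1.0)
        ab = nb.consistency_or(heart_draws, 1, 2)
        ba = nb.consistency_or(heart_draws, 2, 1)
        assert np.allclose(ab * ba, 1.0)

    def test_triangle_identity_per_draw(self, heart_draws):
        ab = nb.consistency_or(heart_draws, 1, 2)
        bc = nb.consistency_or(heart_draws, 2, 3)
        ac = nb.consistency_or(heart_draws, 1, 3)
        assert np.allclose(ab * bc, ac)

    def test_unknown_treatment_rejected(self, heart_draws):
        with pytest.raises(nb.ModelError):
            nb.consistency_or(heart_draws, 1, 9)
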