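"""Shared fixtures: the bundled heart-failure network, toy datasets and
short posterior runs reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import nmabayes as nb
from nmabayes.datasets import load_heart_failure
from nmabayes.sampler import PosteriorDraws


@pytest.fixture(scope="session")
def heart() -> nb.NMADataset:
    return load_heart_failure()


@pytest.fixture(scope="session")
def heart_arrays(heart) -> nb.ModelArrays:
    return nb.prepare_model_arrays(heart)


@pytest.fixture(scope="session")
def heart_draws(heart_arrays) -> PosteriorDraws:
    """Short random-effects consistency run on the heart-failure network —
    long enough for structural/reporting tests, not for tight inference."""
    spec = nb.ModelSpec()
    settings = nb.MCMCSettings(n_chains=2, n_burnin=1500, n_sample=3000,
                               base_seed=7)
    return nb.run_mcmc(spec, heart_arrays, settings)


@pytest.fixture(scope="session")
def toy2() -> nb.NMADataset:
    """Two 2-arm studies comparing two treatments."""
    return nb.dataset_from_rows(
        [
            ("S1", "A", 5, 20),
            ("S1", "B", 10, 20),
            ("S2", "A", 3, 15),
            ("S2", "B", 8, 15),
        ],
        treatment_order=["A", "B"],
        reference="A",
    )


def make_d_draws(d_matrix: np.ndarray, n_treatments: int) -> PosteriorDraws:
    """Wrap an (n_draws, K-1) matrix of basic-parameter values as a two-chain
    consistency PosteriorDraws for ranking/league tests."""
    d_matrix = np.asarray(d_matrix, dtype=float)
    n, km1 = d_matrix.shape
    assert km1 == n_treatments - 1
    half = n // 2
    names = tuple(f"d[{k}]" for k in range(2, n_treatments + 1))
    return PosteriorDraws(
        names=names,
        chains=(d_matrix[:half], d_matrix[half:]),
        spec=nb.ModelSpec(effect="fixed"),
        settings=nb.MCMCSettings(n_chains=2, n_burnin=0, n_sample=max(n - half, 1)),
        arm_labels=(),
        treatment_labels=tuple(f"T{k}" for k in range(1, n_treatments + 1)),
    )
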