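"""Forward simulation of arm-level NMA datasets with known truth.

The generator is the forward version of the random-effects consistency
model: per study a baseline log-odds is drawn uniformly, the non-baseline
trial effects jointly from the exchangeable multivariate normal
(variance sigma^2, covariance sigma^2/2) around the consistency means,
and events binomially.  Drawing the deltas *jointly* (rather than via the
conditional chain the sampler uses) keeps the generator an independent
check of the sampler's conditional decomposition.

An optional scalar ``inconsistency_bump`` adds a fixed offset to the
trial effects of one designated comparison, injecting loop inconsistency
for dev-dev testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import DataError
from .data import Arm, NMADataset, Study


@dataclass(frozen=True)
class SimulationDesign:
    """Layout and truth of a simulated network.

    ``design`` lists the treatment set of each study (1-based indices);
    ``true_d`` holds the K-1 basic parameters (log odds ratios versus
    treatment 1); arm sizes are drawn uniformly from ``arm_size_range``.
    """

    n_treatments: int
    design: tuple[tuple[int, ...], ...]
    true_d: tuple[float, ...]
    true_sigma: float = 0.0
    baseline_logodds_range: tuple[float, float] = (-2.0, -0.5)
    arm_size_range: tuple[int, int] = (200, 400)
    seed: int = 0
    inconsistency_bump: float = 0.0
    bump_comparison: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        k = self.n_treatments
        if len(self.true_d) != k - 1:
            raise DataError("true_d must have K-1 entries")
        if self.true_sigma < 0:
            raise DataError("true_sigma must be non-negative")
        used = set()
        for ts in self.design:
            if len(ts) < 2 or len(set(ts)) != len(ts):
                raise DataError("every study needs >= 2 distinct treatments")
            if not all(1 <= t <= k for t in ts):
                raise DataError("design references unknown treatment")
            used.update(ts)
        if used != set(range(1, k + 1)):
            raise DataError("design must use every treatment")
        # connectivity of the design graph
        comp = {1}
        grown = True
        while grown:
            grown = False
            for ts in self.design:
                if comp & set(ts) and not set(ts) <= comp:
                    comp |= set(ts)
                    grown = True
        if comp != set(range(1, k + 1)):
            raise DataError("design does not connect all treatments")

    @property
    def n_studies(self) -> int:
        return len(self.design)


def two_arm_design(
    n_treatments: int, studies_per_comparison: int = 1
) -> tuple[tuple[int, ...], ...]:
    """A simple connected design: every pair (1,k) plus a (2,3) closing loop
    when K >= 3, repeated ``studies_per_comparison`` times."""
    pairs = [(1, k) for k in range(2, n_treatments + 1)]
    if n_treatments >= 3:
        pairs.append((2, 3))
    return tuple(p for p in pairs for _ in range(studies_per_comparison))


def simulate_dataset(design: SimulationDesign) -> NMADataset:
    """Draw one dataset; deterministic given ``design.seed``."""
    rng = np.random.default_rng(design.seed)
    dfull = np.concatenate([[0.0], np.asarray(design.true_d, dtype=float)])
    studies = []
    for s, ts in enumerate(design.design):
        ts = tuple(sorted(ts))
        m = len(ts) - 1
        mu = rng.uniform(*design.baseline_logodds_range)
        means = np.array([dfull[t - 1] - dfull[ts[0] - 1] for t in ts[1:]])
        if design.bump_comparison is not None and design.inconsistency_bump:
            b0, b1 = design.bump_comparison
            for j, t in enumerate(ts[1:]):
                if (ts[0], t) == (b0, b1):
                    means[j] += design.inconsistency_bump
        s2 = design.true_sigma**2
        cov = s2 / 2 * (np.eye(m) + np.ones((m, m)))
        delta = rng.multivariate_normal(means, cov) if s2 > 0 else means
        logits = np.concatenate([[mu], mu + delta])
        p = 1.0 / (1.0 + np.exp(-logits))
        sizes = rng.integers(
            design.arm_size_range[0], design.arm_size_range[1] + 1, size=len(ts)
        )
        events = rng.binomial(sizes, p)
        # binomial arms can land on all-zero (disconnects nothing but breaks
        # nothing either); keep as-is, the models handle zero cells
        arms = tuple(
            Arm(t, float(e), float(n)) for t, e, n in zip(ts, events, sizes)
        )
        studies.append(Study(f"SIM-{s + 1:03d}", arms))
    labels = tuple(f"T{k}" for k in range(1, design.n_treatments + 1))
    return NMADataset(studies=tuple(studies), treatments=labels, reference=1)
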