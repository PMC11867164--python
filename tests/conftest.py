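"""Shared test helpers: independent simulation oracles and chi-square utilities.

The oracles here are deliberately minimal re-derivations (plain event loops)
kept separate from the package code paths they are used to check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats


def oracle_bdp_size(lam: float, mu: float, t: float, rng, z0: int = 1) -> int:
    """Plain event-driven LBDP population size at t (independent oracle)."""
    n = z0
    now = 0.0
    total = lam + mu
    p_birth = lam / total
    while n > 0:
        now += rng.exponential(1.0 / (total * n))
        if now >= t:
            break
        n += 1 if rng.random() < p_birth else -1
    return n


def oracle_yule_sizes(lam: float, t: float, reps: int, rng, z0: int = 1) -> np.ndarray:
    """Vectorized pure-birth population sizes at t for many replicates.

    Round j draws the holding time at size j for all still-active replicates;
    a replicate stops once its cumulative time passes t.
    """
    sizes = np.full(reps, z0, dtype=int)
    clock = np.zeros(reps)
    active = np.arange(reps)
    j = z0
    while active.size:
        clock[active] += rng.exponential(1.0 / (lam * j), size=active.size)
        still = clock[active] < t
        sizes[active[still]] += 1
        active = active[still]
        j += 1
    return sizes


def chisq_pvalue(observed: np.ndarray, probs: np.ndarray, min_expected: float = 5.0) -> float:
    """Chi-square GoF p-value with small-expectation bins merged into the tail."""
    n = observed.sum()
    expected = probs * n
    # merge from the right until every bin has enough mass
    obs, exp = list(observed), list(expected)
    while len(obs) > 2 and exp[-1] < min_expected:
        exp[-2] += exp.pop()
        obs[-2] += obs.pop()
    obs, exp = np.asarray(obs, dtype=float), np.asarray(exp)
    exp = exp * obs.sum() / exp.sum()
    return float(stats.chisquare(obs, exp).pvalue)


@pytest.fixture(scope="session")
def small_cell_config():
    from bdtree import CellSimConfig

    return CellSimConfig(split_prob=0.7, mutation_rate=5.0, target_size=60, sample_size=10)
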