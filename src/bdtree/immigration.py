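"""Linear birth-death process with Poisson immigration and the Ewens sampling formula.

New families arrive as a homogeneous Poisson process of rate ``theta``; each
family then grows as an independent linear birth-death process from a single
founder.  Marking each arrival with its family size at the horizon makes the
counts C_j(t) (number of families of size j) independent Poisson variables,
the total population size Z(t) negative binomial, and the family-size
configuration conditional on Z(t) = n the Ewens sampling formula with
concentration theta/lam.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import integrate, special, stats

from .bdp_core import BDParams, beta_alpha, bdp_pmf

__all__ = [
    "FamilyConfig",
    "FamilyCounts",
    "expected_family_count",
    "expected_family_count_quadrature",
    "expected_families_alive",
    "simulate_bdp_size",
    "simulate_family_process",
    "population_size_pmf",
    "population_size_mean",
    "ewens_pmf",
    "partitions",
]


@dataclass(frozen=True)
class FamilyConfig:
    """Immigration rate theta, per-family growth rates, and the horizon t."""

    immigration_rate: float
    growth: BDParams
    horizon: float

    def __post_init__(self) -> None:
        if not self.immigration_rate > 0:
            raise ValueError("immigration_rate must be > 0")
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")

    @property
    def kappa(self) -> float:
        """Concentration parameter theta/lam of the conditioned family counts."""
        return self.immigration_rate / self.growth.birth_rate


@dataclass
class FamilyCounts:
    """Family-size configuration at the horizon.

    ``counts[j-1]`` is C_j, the number of surviving families of size j;
    ``n_arrivals`` the total number of immigration events (including families
    that have since died out).
    """

    counts: np.ndarray
    n_arrivals: int

    @property
    def population_size(self) -> int:
        """Z = sum_j j C_j."""
        j = np.arange(1, len(self.counts) + 1)
        return int(np.dot(j, self.counts))

    @property
    def n_families(self) -> int:
        """F = sum_j C_j, families alive at the horizon."""
        return int(self.counts.sum())

    @property
    def n_extinct(self) -> int:
        return self.n_arrivals - self.n_families


def expected_family_count(j: int, config: FamilyConfig) -> float:
    """E C_j(t): expected number of families of size j at the horizon.

    For j >= 1 this is (theta/lam) beta(t)^j / j.  For j = 0 it is the
    expected number of families that arrived and went extinct by t,
    theta*t + (theta/lam) log(1 - beta(t)) — a cumulative count, which grows
    with t (it is not bounded by 1).
    """
    if j < 0:
        raise ValueError("j must be >= 0")
    theta, t = config.immigration_rate, config.horizon
    b, _ = beta_alpha(t, config.growth)
    kappa = config.kappa
    if j == 0:
        return theta * t + kappa * math.log1p(-b)
    return kappa * b**j / j


def expected_family_count_quadrature(j: int, config: FamilyConfig) -> float:
    """E C_j(t) = theta * int_0^t p_{1j}(t-u) du, by adaptive quadrature.

    Cross-check path for the closed form; integrates the single-founder
    transition probability over arrival times.
    """
    if j < 0:
        raise ValueError("j must be >= 0")
    theta, t = config.immigration_rate, config.horizon
    if t == 0:
        return 0.0
    val, _ = integrate.quad(
        lambda v: bdp_pmf(j, v, config.growth) if v > 0 else (1.0 if j == 1 else 0.0),
        0.0,
        t,
        epsabs=1e-12,
        limit=200,
    )
    return theta * val


def expected_families_alive(config: FamilyConfig) -> float:
    """Poisson mean of F(t) = C_1 + C_2 + ...: theta * int_0^t (1 - p10(u)) du."""
    theta, t = config.immigration_rate, config.horizon
    if t == 0:
        return 0.0
    val, _ = integrate.quad(
        lambda u: 1.0 - beta_alpha(u, config.growth)[1], 0.0, t, epsabs=1e-12, limit=200
    )
    return theta * val


def simulate_bdp_size(
    params: BDParams, t: float, z0: int = 1, rng: np.random.Generator | None = None, seed=None
) -> int:
    """Event-driven simulation of the LBDP population size at time t."""
    rng = np.random.default_rng(seed) if rng is None else rng
    lam, mu = params.birth_rate, params.death_rate
    total = lam + mu
    p_split = lam / total
    n = z0
    now = 0.0
    while n > 0:
        now += rng.exponential(1.0 / (total * n))
        if now >= t:
            break
        n += 1 if rng.random() < p_split else -1
    return n


def simulate_family_process(
    config: FamilyConfig, seed=None, rng: np.random.Generator | None = None
) -> FamilyCounts:
    """One realization of the immigration model: arrivals, growth, sizes at t.

    Arrivals are Poisson(theta * t) placed uniformly on (0, t); each family
    then evolves as an independent single-founder LBDP for its remaining time.
    Families per-family rather than jointly, mirroring the marked-Poisson
    independence structure.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    theta, t = config.immigration_rate, config.horizon
    n_arrivals = rng.poisson(theta * t)
    sizes = [
        simulate_bdp_size(config.growth, t - u, rng=rng)
        for u in rng.uniform(0.0, t, size=n_arrivals)
    ]
    max_size = max(sizes, default=0)
    counts = np.zeros(max_size, dtype=int)
    for s in sizes:
        if s > 0:
            counts[s - 1] += 1
    return FamilyCounts(counts=counts, n_arrivals=int(n_arrivals))


def population_size_pmf(j, config: FamilyConfig):
    """P(Z(t) = j | Z(0) = 0): negative binomial with shape theta/lam.

    C(j + theta/lam - 1, j) (1 - beta)^{theta/lam} beta^j.
    """
    j_arr = np.asarray(j)
    if np.any(j_arr < 0):
        raise ValueError("j must be >= 0")
    b, _ = beta_alpha(config.horizon, config.growth)
    out = stats.nbinom.pmf(j_arr, config.kappa, 1.0 - b)
    return out if out.ndim else float(out)


def population_size_mean(config: FamilyConfig) -> float:
    """E Z(t) = theta (e^{(lam-mu)t} - 1)/(lam - mu), or theta*t when lam = mu."""
    theta, t = config.immigration_rate, config.horizon
    lam, mu = config.growth.birth_rate, config.growth.death_rate
    if config.growth.is_critical:
        return theta * t
    return theta * math.expm1((lam - mu) * t) / (lam - mu)


def ewens_pmf(c: Sequence[int], kappa: float) -> float:
    """Ewens sampling formula: probability of the multiplicity vector c.

    ``c[j-1]`` is the number of families of size j; with n = sum_j j c_j the
    probability is  n!/(kappa)_(n) * prod_j (kappa/j)^{c_j} / c_j!  where
    (kappa)_(n) is the rising factorial.  Depends on the immigration model
    only through kappa = theta/lam.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    c_arr = np.asarray(c, dtype=int)
    if c_arr.ndim != 1 or np.any(c_arr < 0):
        raise ValueError("c must be a vector of nonnegative multiplicities")
    j = np.arange(1, len(c_arr) + 1)
    n = int(np.dot(j, c_arr))
    if n < 1:
        raise ValueError("partition must have n = sum j*c_j >= 1")
    if n != len(c_arr):
        raise ValueError(
            f"inconsistent partition: dense vector c_1..c_n must have length n, "
            f"got length {len(c_arr)} with sum j*c_j = {n}"
        )
    log_p = (
        special.gammaln(n + 1)
        - (special.gammaln(kappa + n) - special.gammaln(kappa))
        + np.sum(c_arr * (math.log(kappa) - np.log(j)) - special.gammaln(c_arr + 1))
    )
    return float(math.exp(log_p))


def partitions(n: int) -> Iterator[tuple[int, ...]]:
    """All partitions of n as multiplicity vectors (c_1, ..., c_n).

    Exhaustive enumeration, used to normalize/tabulate the Ewens formula.
    """
    if n < 1:
        raise ValueError("n must be >= 1")

    def _gen(remaining: int, max_part: int, acc: list[int]) -> Iterator[tuple[int, ...]]:
        if remaining == 0:
            yield tuple(acc)
            return
        for part in range(min(remaining, max_part), 0, -1):
            for count in range(remaining // part, 0, -1):
                acc2 = list(acc)
                acc2[part - 1] = count
                yield from _gen(remaining - part * count, part - 1, acc2)

    yield from _gen(n, n, [0] * n)
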