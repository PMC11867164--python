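"""Closed-form laws for homogeneous and time-changed linear birth-death processes.

A linear birth-death process (LBDP) has population-level rates ``n*lam`` (birth)
and ``n*mu`` (death) when ``n`` individuals are alive.  Starting from a single
individual the population size at time ``t`` is geometric on {1, 2, ...} with an
atom at 0 for extinction; the geometric parameter ``beta(t)`` and extinction
probability ``alpha(t)`` are the two rate functions everything downstream is
built from.  The pure-birth (Yule, ``mu = 0``) case and its deterministic
time-change to an inhomogeneous split rate are handled as special cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import integrate, stats

__all__ = [
    "BDParams",
    "yule_pmf",
    "yule_negbin_pmf",
    "beta_alpha",
    "bdp_pmf",
    "extinction_prob",
    "inhomogeneous_yule_pmf",
    "integrated_rate",
]

# Relative |lam - mu| threshold below which the critical (lam == mu) closed
# form is used; eq. beta(t) = lam(e^{(lam-mu)t}-1)/(lam e^{(lam-mu)t}-mu) has a
# removable singularity there and cancels catastrophically nearby.
_CRITICAL_RTOL = 1e-8

# Tail mass below which infinite sums over the geometric tail are truncated.
_TAIL_TOL = 1e-12

# Absolute tolerance for the quadrature of the integrated split rate rho(t).
_QUAD_ATOL = 1e-10


@dataclass(frozen=True)
class BDParams:
    """Per-capita rates of a linear birth-death process.

    Parameters
    ----------
    birth_rate : float
        Per-capita split rate ``lam`` (1/time), strictly positive.
    death_rate : float
        Per-capita death rate ``mu`` (1/time), nonnegative.  ``mu = 0`` gives
        the Yule (pure birth) process.
    """

    birth_rate: float
    death_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.birth_rate > 0:
            raise ValueError(f"birth_rate must be > 0, got {self.birth_rate}")
        if self.death_rate < 0:
            raise ValueError(f"death_rate must be >= 0, got {self.death_rate}")

    @property
    def is_critical(self) -> bool:
        """True when lam and mu are equal to within the numerical switch."""
        return abs(self.birth_rate - self.death_rate) <= _CRITICAL_RTOL * self.birth_rate


def yule_pmf(n, t: float, lam: float):
    """P(Z(t) = n | Z(0) = 1) for a Yule process with split rate ``lam``.

    The population size is geometric: ``e^{-lam t} (1 - e^{-lam t})^{n-1}``
    for n = 1, 2, ..., with mean ``e^{lam t}``.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if t < 0:
        raise ValueError("t must be >= 0")
    n_arr = np.asarray(n)
    if np.any(n_arr < 1):
        raise ValueError("n must be >= 1")
    # log-space for large n*lam*t
    log_p = -lam * t
    if t == 0:
        out = np.where(n_arr == 1, 1.0, 0.0)
        return out if out.ndim else float(out)
    log_q = math.log(-math.expm1(-lam * t))
    out = np.exp(log_p + (n_arr - 1) * log_q)
    return out if out.ndim else float(out)


def yule_negbin_pmf(n, t: float, lam: float, r: int):
    """P(Z(t) = n | Z(0) = r): negative binomial for r independent Yule lines.

    ``C(n-1, r-1) e^{-r lam t} (1 - e^{-lam t})^{n-r}`` for n >= r; zero below r.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    n_arr = np.asarray(n)
    p_success = math.exp(-lam * t)
    # number of failures = n - r, r successes each with prob e^{-lam t}
    out = np.where(n_arr >= r, stats.nbinom.pmf(n_arr - r, r, p_success), 0.0)
    return out if out.ndim else float(out)


def beta_alpha(t: float, params: BDParams) -> tuple[float, float]:
    """Rate functions (beta(t), alpha(t)) of the LBDP started from one individual.

    beta is the geometric parameter of the positive part of the population-size
    law, alpha the extinction-by-t probability:

    * lam != mu:  beta = lam(e^{(lam-mu)t} - 1) / (lam e^{(lam-mu)t} - mu),
      alpha = (mu/lam) beta
    * lam == mu:  beta = alpha = lam t / (1 + lam t)

    Both lie in [0, 1) for finite t, beta(0) = alpha(0) = 0, and
    d beta/dt = lam (1 - alpha)(1 - beta).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    lam, mu = params.birth_rate, params.death_rate
    if params.is_critical:
        b = lam * t / (1.0 + lam * t)
        return b, b
    r = lam - mu
    # expm1 keeps precision for small r*t; division is stable away from lam==mu
    e = math.expm1(r * t)
    b = lam * e / (lam * (e + 1.0) - mu)
    return b, (mu / lam) * b


def bdp_pmf(m, t: float, params: BDParams):
    """P(Z(t) = m | Z(0) = 1) for the linear birth-death process.

    p_{10}(t) = alpha(t); p_{1m}(t) = (1 - alpha)(1 - beta) beta^{m-1}, m >= 1.
    """
    if t <= 0:
        raise ValueError("t must be > 0")
    m_arr = np.asarray(m)
    if np.any(m_arr < 0):
        raise ValueError("m must be >= 0")
    b, a = beta_alpha(t, params)
    if b == 0.0:
        positive = np.where(m_arr == 1, 1.0 - a, 0.0)
    else:
        positive = (1.0 - a) * (1.0 - b) * np.exp((m_arr - 1) * math.log(b))
    out = np.where(m_arr == 0, a, positive)
    return out if out.ndim else float(out)


def bdp_support_upper(t: float, params: BDParams, tail_tol: float = _TAIL_TOL) -> int:
    """Smallest m such that P(Z(t) > m) < tail_tol, from the geometric tail."""
    b, a = beta_alpha(t, params)
    if b == 0.0:
        return 1
    # tail mass beyond m is (1 - alpha) * beta^m
    m = math.log(tail_tol / max(1.0 - a, tail_tol)) / math.log(b)
    return max(1, int(math.ceil(m)))


def extinction_prob(params: BDParams, m0: int = 1) -> float:
    """Eventual extinction probability min{1, (mu/lam)^{m0}} from m0 individuals."""
    if m0 < 1:
        raise ValueError("m0 must be >= 1")
    lam, mu = params.birth_rate, params.death_rate
    if mu >= lam:
        return 1.0
    return (mu / lam) ** m0


def integrated_rate(rate_fn: Callable[[float], float], t: float) -> float:
    """rho(t) = integral of a nonnegative split rate over [0, t], by adaptive quadrature."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return 0.0
    probe = np.linspace(0.0, t, 33)
    if any(rate_fn(u) < 0 for u in probe):
        raise ValueError("rate_fn must be nonnegative on [0, t]")
    rho, _ = integrate.quad(rate_fn, 0.0, t, epsabs=_QUAD_ATOL, limit=200)
    if rho < 0:
        raise ValueError("integrated rate is negative; rate_fn must be nonnegative")
    return rho


def inhomogeneous_yule_pmf(n, t: float, rate_fn: Callable[[float], float]):
    """Population-size pmf of a pure-birth process with time-varying split rate.

    The process is a deterministic time-change of a unit-rate Yule process:
    Z~(t) = Z(rho(t)) with rho(t) = int_0^t lam(u) du, so the pmf is geometric
    with e^{-rho(t)} in place of e^{-lam t}.
    """
    rho = integrated_rate(rate_fn, t)
    if rho == 0.0:
        n_arr = np.asarray(n)
        if np.any(n_arr < 1):
            raise ValueError("n must be >= 1")
        out = np.where(n_arr == 1, 1.0, 0.0)
        return out if out.ndim else float(out)
    return yule_pmf(n, 1.0, rho)
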