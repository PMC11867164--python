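"""Fisher's multiple-sampling variance under a Yule-with-immigration model.

Specimens arrive as a unit-rate Yule process per family, families immigrate as
a Poisson process of rate ``theta`` (time scaled so the split rate lam = 1;
rescale time externally for general lam).  A specimen is counted at its birth
or arrival instant, so the species found in the consecutive windows (0, t1]
and (t1, t2] are F_1 = arrivals in (0, t1] (each family's first specimen is
its founder) and F_2 = arrivals in (t1, t2] plus the overlap count F(t1, t2) —
families arriving before t1 with offspring born in (t1, t2].

The overlap count F(a, b) is Poisson with mean theta*log(e^b - e^a + 1); its
covariances across disjoint windows are explicit, which gives a closed form
for the expected sample variance E V2 = E (F_1 - F_2)^2 / 2 of the species
counts in two consecutive samples.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "overlap_mean",
    "overlap_cov",
    "ev2_mean_times",
    "ev2_mean_sizes",
    "ev2_equal_sizes",
    "choose_times",
    "yule_birth_times",
    "simulate_specimen_times",
    "simulate_two_sample_v2",
]


def overlap_mean(a: float, b: float, theta: float) -> float:
    """Poisson mean of F(a, b), families arriving in (0, a) with offspring in (a, b).

    theta * log(e^b - e^a + 1).  Restricted to a > 0: at a = 0 the printed
    formula degenerates to theta*b, the plain arrival count, which is not an
    overlap count of previously-arrived families.
    """
    if a <= 0 or b < a:
        raise ValueError("need 0 < a <= b")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    return theta * math.log(math.exp(b) - math.exp(a) + 1.0)


def overlap_cov(a: float, b: float, c: float, d: float, theta: float) -> float:
    """Cov(F(a,b), F(c,d)) for ordered windows 0 <= a < b <= c < d.

    theta * log((e^b - e^a + 1)(e^d - e^c + 1) / (e^d - e^c + e^b - e^a + 1)).
    """
    if not (0 <= a < b <= c < d):
        raise ValueError("need 0 <= a < b <= c < d")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    x = math.exp(b) - math.exp(a)
    y = math.exp(d) - math.exp(c)
    return theta * math.log((x + 1.0) * (y + 1.0) / (x + y + 1.0))


def ev2_mean_times(t1: float, t2: float, theta: float) -> float:
    """E V2 = E (F_1 - F_2)^2 / 2 for sampling windows (0, t1], (t1, t2].

    (1/2) { theta log(e^{2 t2} e^{-t1} / (e^{t2} - e^{t1} + 1))
          + theta^2 log^2(e^{t1} / (e^{t2} - e^{t1} + 1)) }.
    """
    if not 0 < t1 < t2:
        raise ValueError("need 0 < t1 < t2")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    w = math.exp(t2) - math.exp(t1) + 1.0
    lin = theta * (2.0 * t2 - t1 - math.log(w))
    quad = theta**2 * (t1 - math.log(w)) ** 2
    return 0.5 * (lin + quad)


def choose_times(n1: float, n2: float, theta: float) -> tuple[float, float]:
    """Times at which the expected specimen counts are n1 and n1 + n2.

    Inverts E Z(t) = theta (e^t - 1): t1 = log((n1 + theta)/theta),
    t2 = log((n1 + n2 + theta)/theta).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be > 0")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    t1 = math.log(n1 + theta) - math.log(theta)
    t2 = math.log(n1 + n2 + theta) - math.log(theta)
    return t1, t2


def ev2_mean_sizes(n1: float, n2: float, theta: float) -> float:
    """E V2 for consecutive samples of expected sizes n1, n2.

    (1/2){ theta log((n1+n2+theta)^2 / ((n1+theta)(n2+theta)))
         + theta^2 log^2((n1+theta)/(n2+theta)) }.
    """
    if n1 <= 0 or n2 <= 0 or theta <= 0:
        raise ValueError("sizes and theta must be > 0")
    s = n1 + n2 + theta
    lin = theta * math.log(s * s / ((n1 + theta) * (n2 + theta)))
    quad = theta**2 * math.log((n1 + theta) / (n2 + theta)) ** 2
    return 0.5 * (lin + quad)


def ev2_equal_sizes(n: float, theta: float) -> float:
    """Equal-size reduction: E V2 = theta log((2n + theta)/(n + theta)).

    Approaches theta*log(2) from below as n grows.  (For two independent
    samples of size n from replicate populations the analogue is theta*log(n);
    that scenario has no simulator here.)
    """
    if n <= 0 or theta <= 0:
        raise ValueError("n and theta must be > 0")
    return theta * math.log((2.0 * n + theta) / (n + theta))


def yule_birth_times(
    horizon: float, rng: np.random.Generator, _chunk: int = 16
) -> np.ndarray:
    """Birth-event times of a unit-rate Yule process from one founder on (0, horizon].

    The k-th inter-birth gap is exponential with rate k; draws are chunked for
    speed since the event count grows like e^horizon.
    """
    if horizon <= 0:
        return np.empty(0)
    pieces = []
    k = 1
    now = 0.0
    while True:
        gaps = rng.exponential(size=_chunk) / np.arange(k, k + _chunk)
        ts = now + np.cumsum(gaps)
        cut = int(np.searchsorted(ts, horizon, side="right"))
        pieces.append(ts[:cut])
        if cut < _chunk:
            return np.concatenate(pieces) if len(pieces) > 1 else pieces[0]
        now = float(ts[-1])
        k += _chunk


def simulate_specimen_times(
    theta: float, horizon: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """One run of the Yule-with-immigration specimen process up to the horizon.

    Returns, per family, the sorted times of its specimens: the arrival instant
    followed by the family's birth events.
    """
    n_arrivals = rng.poisson(theta * horizon)
    arrivals = np.sort(rng.uniform(0.0, horizon, size=n_arrivals))
    out = []
    for u in arrivals:
        births = u + yule_birth_times(horizon - u, rng)
        out.append(np.concatenate(([u], births)))
    return out


def simulate_two_sample_v2(
    n1: float, n2: float, theta: float, reps: int, seed=None, rng=None
) -> dict:
    """Monte-Carlo estimate of E V2 for consecutive samples of sizes n1, n2.

    Simulates the specimen process to t2 from :func:`choose_times`; per rep,
    F_1 and F_2 count the distinct families with at least one specimen in
    (0, t1] and (t1, t2] respectively, and V2 = (F_1 - F_2)^2 / 2.

    Returns a dict with keys ``mean``, ``se``, ``analytic`` (the closed form),
    ``mean_f1``, ``mean_f2``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    t1, t2 = choose_times(n1, n2, theta)
    v2 = np.empty(reps)
    f1s = np.empty(reps, dtype=int)
    f2s = np.empty(reps, dtype=int)
    for r in range(reps):
        f1 = f2 = 0
        for times in simulate_specimen_times(theta, t2, rng):
            if times[0] <= t1:
                f1 += 1
                if times[-1] > t1:  # sorted: any specimen after t1?
                    f2 += 1
            else:
                f2 += 1
        f1s[r], f2s[r] = f1, f2
        v2[r] = 0.5 * (f1 - f2) ** 2
    return {
        "mean": float(v2.mean()),
        "se": float(v2.std(ddof=1) / math.sqrt(reps)),
        "analytic": ev2_mean_sizes(n1, n2, theta),
        "mean_f1": float(f1s.mean()),
        "mean_f2": float(f2s.mean()),
    }
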