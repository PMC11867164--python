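"""Somatic-evolution simulator: birth-death cell population, sampled ancestry, SFS.

A population of cells grows from a single founder.  Each cell waits an
exponential time with rate ``event_rate`` and then divides with probability
``split_prob`` (two daughters) or dies; equivalently a linear birth-death
process with per-cell birth rate p*lam and death rate (1-p)*lam.  Growth
continues until N cells are alive at once; runs that die out first are
discarded and restarted.  A uniform sample of n cells is taken at the freeze
time, neutral mutations are dropped on the branches of the sample's ancestral
tree under an infinite-sites model of rate ``mutation_rate``, and the
resulting site frequency spectrum (SFS) f_1..f_n is condensed into the
summary vector (S, b_1..b_9, truncal) used for likelihood-free inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tree_sim import TimedTree, reduce_to_leaves

__all__ = [
    "CellSimConfig",
    "SFS",
    "SummaryStats",
    "try_grow_population",
    "grow_population",
    "sample_tree",
    "drop_mutations",
    "summarize",
    "simulate_dataset",
    "SUMMARY_COLUMNS",
]

SUMMARY_COLUMNS = ["S"] + [f"b{k}" for k in range(1, 10)] + ["truncal"]

_SPLIT, _DEATH, _OBSERVED = "split", "death", "observed"


@dataclass(frozen=True)
class CellSimConfig:
    """Parameters of the cell-population simulator.

    split_prob : division probability p in (0, 1); the population is
        supercritical for p > 1/2 and survives forever with probability
        (2p - 1)/p.
    event_rate : per-cell event rate lam (1/time); fixed to 1 by convention,
        which sets the time unit.
    target_size : N, the concurrent cell count at which the population is frozen.
    sample_size : n cells sampled uniformly without replacement for analysis.
    mutation_rate : theta, mutations per unit branch time (or per division when
        ``per_division`` is set).
    include_stem : keep the branch from the founder to the sample MRCA, so
        truncal mutations (carried by every sampled cell) can arise.
    per_division : use a per-division mutation clock, Poisson(theta * number of
        divisions on the branch), instead of the default time clock
        Poisson(theta * branch duration).
    max_attempts : cap on extinction restarts during growth.
    """

    split_prob: float
    mutation_rate: float
    target_size: int = 1000
    sample_size: int = 100
    event_rate: float = 1.0
    include_stem: bool = True
    per_division: bool = False
    max_attempts: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.split_prob < 1.0:
            raise ValueError("split_prob must be in (0, 1)")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")
        if not 2 <= self.sample_size <= self.target_size:
            raise ValueError("need 2 <= sample_size <= target_size")
        if self.event_rate <= 0:
            raise ValueError("event_rate must be > 0")


@dataclass
class SFS:
    """Site frequency spectrum of a sample of size n.

    ``f[j-1]`` is f_j, the number of mutations carried by exactly j of the n
    sampled cells; f_n are the truncal mutations.
    """

    f: np.ndarray

    @property
    def n(self) -> int:
        return len(self.f)

    @property
    def total(self) -> int:
        """S = f_1 + ... + f_n."""
        return int(self.f.sum())

    @property
    def truncal(self) -> int:
        return int(self.f[-1])


@dataclass
class SummaryStats:
    """The 11-dimensional summary (S, b_1..b_9, truncal count).

    b_k is the proportion of the S mutations with sample frequency j/n in the
    bin ((k-1)/10, k/10]; b_10 is derived (1 - b_1 - ... - b_9 when S > 0) and
    omitted from the vector because the truncal count covers the top bin's
    informative part.
    """

    S: int
    b: np.ndarray  # b_1..b_9
    truncal: int
    attempts: int = 1  # growth restarts used (not part of the vector)
    params: dict = field(default_factory=dict)

    def vector(self) -> np.ndarray:
        return np.concatenate(([float(self.S)], self.b, [float(self.truncal)]))


def try_grow_population(config: CellSimConfig, rng: np.random.Generator) -> TimedTree | None:
    """One growth attempt: the complete tree if N cells are reached, else None.

    The tree is frozen at the instant the N-th concurrent cell appears (every
    extant cell's end_time is that instant).
    """
    p, lam, n_target = config.split_prob, config.event_rate, config.target_size
    tree = TimedTree(t=math.inf, flavor="complete")
    tree.add_node(-1, 0.0, label=1)
    extant = [0]
    next_label = 2
    now = 0.0
    while extant:
        now += rng.exponential(1.0 / (lam * len(extant)))
        i = rng.integers(len(extant))
        v = extant[i]
        extant[i] = extant[-1]
        extant.pop()
        tree.end_time[v] = now
        if rng.random() < p:
            tree.end_reason[v] = _SPLIT
            extant.append(tree.add_node(v, now, label=tree.label[v]))
            extant.append(tree.add_node(v, now, label=next_label))
            next_label += 1
            if len(extant) == n_target:
                break
        else:
            tree.end_reason[v] = _DEATH
    if not extant:
        return None
    tree.t = now
    for v in extant:
        tree.end_time[v] = now
        tree.end_reason[v] = _OBSERVED
    return tree


def grow_population(
    config: CellSimConfig, seed=None, rng: np.random.Generator | None = None
) -> TimedTree:
    """Grow the cell population to N concurrent cells; restart on extinction.

    Attempts that die out before reaching N are discarded and the growth is
    restarted (with the same parameters) on a fresh stretch of the RNG stream.
    The number of attempts used is recorded in ``tree.metadata["attempts"]``;
    its mean over runs is ~ p/(2p - 1), the reciprocal survival probability.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed) if rng is None else rng
    for attempt in range(1, config.max_attempts + 1):
        tree = try_grow_population(config, rng)
        if tree is not None:
            tree.metadata["attempts"] = attempt
            return tree
    p, n_target = config.split_prob, config.target_size
    raise RuntimeError(
        f"population failed to reach {n_target} cells in {config.max_attempts} attempts "
        f"(split_prob={p}; expected attempts ~ {p / (2 * p - 1):.1f})"
        if p > 0.5
        else f"population failed to reach {n_target} cells in {config.max_attempts} "
        f"attempts (split_prob={p} is subcritical)"
    )


def sample_tree(
    population: TimedTree, n: int, seed=None, rng: np.random.Generator | None = None
) -> TimedTree:
    """Ancestral tree of a uniform sample of n extant cells, stem included.

    The sampled cells' ancestry is pruned and unary-suppressed; the stem
    branch from the founder (time 0) to the sample MRCA is retained so that
    truncal mutations are representable.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    leaves = population.leaves()
    if n > len(leaves):
        raise ValueError(f"sample size {n} exceeds extant count {len(leaves)}")
    chosen = rng.choice(len(leaves), size=n, replace=False)
    sub = reduce_to_leaves(population, [leaves[i] for i in chosen])
    assert sub is not None
    return sub


def _descendant_counts(tree: TimedTree) -> np.ndarray:
    """Number of sampled leaves below (and including) each node."""
    counts = np.zeros(len(tree), dtype=int)
    for v in range(len(tree) - 1, -1, -1):  # children have larger ids than parents
        if tree.end_reason[v] == _OBSERVED:
            counts[v] = 1
        if tree.parent[v] >= 0:
            counts[tree.parent[v]] += counts[v]
    return counts


def drop_mutations(
    tree: TimedTree,
    theta: float,
    seed=None,
    rng: np.random.Generator | None = None,
    include_stem: bool = True,
    per_division: bool = False,
) -> SFS:
    """Drop infinite-sites mutations on the sampled ancestral tree.

    Each branch receives Poisson(theta * duration) mutations (or
    Poisson(theta * divisions) under the per-division clock); every mutation is
    carried by all sampled descendants of the branch, so a branch with d
    descendants adds to f_d.  Stem mutations have d = n (truncal).
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    rng = np.random.default_rng(seed) if rng is None else rng
    n = tree.n_extant()
    desc = _descendant_counts(tree)
    if per_division:
        if not tree.divisions:
            raise ValueError("tree carries no division counts; reduce a complete tree first")
        exposure = np.asarray(tree.divisions, dtype=float)
    else:
        exposure = tree.branch_lengths()
    if not include_stem:
        exposure = exposure.copy()
        exposure[np.asarray(tree.parent) == -1] = 0.0
    muts = rng.poisson(theta * exposure)
    f = np.zeros(n, dtype=int)
    np.add.at(f, desc - 1, muts)
    return SFS(f=f)


def summarize(sfs: SFS, n: int | None = None) -> SummaryStats:
    """Condense an SFS into the summary vector (S, b_1..b_9, truncal).

    Mutations at sample frequency j/n are assigned to the half-open bin
    ((k-1)/10, k/10], i.e. k = ceil(10 j / n); proportions b_k = (bin mass)/S.
    All b_k are 0 when S = 0.
    """
    n = sfs.n if n is None else n
    if n != sfs.n:
        raise ValueError(f"SFS has length {sfs.n}, expected n={n}")
    s = sfs.total
    b = np.zeros(10)
    if s > 0:
        j = np.arange(1, n + 1)
        k = np.ceil(10.0 * j / n).astype(int)
        np.add.at(b, k - 1, sfs.f / s)
    return SummaryStats(S=s, b=b[:9].copy(), truncal=sfs.truncal)


def simulate_dataset(
    config: CellSimConfig, seed=None, rng: np.random.Generator | None = None
) -> SummaryStats:
    """Full pipeline: grow to N, sample n cells, mutate, summarize.

    Deterministic given a seed.  The returned SummaryStats records the number
    of growth attempts and the generating parameters.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed) if rng is None else rng
    population = grow_population(config, rng=rng)
    sub = sample_tree(population, config.sample_size, rng=rng)
    sfs = drop_mutations(
        sub,
        config.mutation_rate,
        rng=rng,
        include_stem=config.include_stem,
        per_division=config.per_division,
    )
    out = summarize(sfs)
    out.attempts = population.metadata["attempts"]
    out.params = {"p": config.split_prob, "theta": config.mutation_rate}
    return out
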