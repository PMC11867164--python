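"""Birth-death tree simulation: complete trees, pruning, and direct reconstructed trees.

Two routes to the ancestral tree of the individuals alive at time ``t``:

1. forward simulation of the *complete* tree (every birth and death event),
   followed by pruning of the lineages that die before ``t``;
2. direct simulation of the *reconstructed* tree of ``n`` survivors, using the
   fact that conditional on n lineages at t the split times are the increasing
   order statistics of n-1 i.i.d. draws from the density
   g(u) proportional to lam (1 - alpha(t-u)) (1 - beta(t-u)), with CDF
   G(u) = 1 - beta(t-u)/beta(t), invertible in closed form.

Both routes produce the same law for the split times; the direct sampler avoids
the cost of rejection on the extant count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .bdp_core import BDParams, beta_alpha

__all__ = [
    "TimedTree",
    "simulate_complete_tree",
    "reduce_to_leaves",
    "prune_to_reconstructed",
    "sample_yule_split_times",
    "reconstructed_split_cdf",
    "reconstructed_split_ppf",
    "simulate_reconstructed_tree",
]

_SPLIT, _DEATH, _OBSERVED = "split", "death", "observed"


@dataclass
class TimedTree:
    """Rooted binary timed tree stored as parallel per-node arrays.

    Node 0 is the root (the stem lineage starting at time 0).  A split node has
    exactly two children whose ``birth_time`` equals the parent's ``end_time``.
    ``label`` carries the species/lineage number in order of lineage creation:
    at a split the first child continues the parent's lineage label and the
    second child starts a new one.

    Attributes
    ----------
    parent : list[int]        parent node id, -1 for the root
    birth_time, end_time : list[float]
    end_reason : list[str]    one of {"split", "death", "observed"}
    label : list[int | None]  lineage label; None for reduced internal nodes
    t : float                 observation horizon
    flavor : str              "complete" or "reconstructed"
    stem_from_origin : bool   reconstructed trees keep the stem [0, first split]
    """

    t: float
    flavor: str
    parent: list[int] = field(default_factory=list)
    birth_time: list[float] = field(default_factory=list)
    end_time: list[float] = field(default_factory=list)
    end_reason: list[str] = field(default_factory=list)
    label: list = field(default_factory=list)
    stem_from_origin: bool = True
    # number of original division events collapsed into each branch of a
    # reduced tree (filled by reduce_to_leaves; empty for simulated trees)
    divisions: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def add_node(self, parent: int, birth: float, label=None) -> int:
        self.parent.append(parent)
        self.birth_time.append(birth)
        self.end_time.append(math.nan)
        self.end_reason.append("")
        self.label.append(label)
        return len(self.parent) - 1

    def __len__(self) -> int:
        return len(self.parent)

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(len(self))]
        for v, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(v)
        return kids

    def leaves(self) -> list[int]:
        """Nodes observed alive at the horizon t."""
        return [v for v, r in enumerate(self.end_reason) if r == _OBSERVED]

    def n_extant(self) -> int:
        return len(self.leaves())

    def split_times(self) -> np.ndarray:
        """Sorted times of the binary splits."""
        return np.sort(
            [self.end_time[v] for v, r in enumerate(self.end_reason) if r == _SPLIT]
        )

    def branch_lengths(self) -> np.ndarray:
        return np.asarray(self.end_time) - np.asarray(self.birth_time)

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def validate(self) -> None:
        kids = self.children()
        for v in range(len(self)):
            r = self.end_reason[v]
            n_kids = len(kids[v])
            if r == _SPLIT and n_kids != 2:
                raise ValueError(f"split node {v} has {n_kids} children, expected 2")
            if r in (_DEATH, _OBSERVED) and n_kids != 0:
                raise ValueError(f"terminal node {v} has children")
            if not 0.0 <= self.birth_time[v] <= self.end_time[v] <= self.t + 1e-12:
                raise ValueError(f"node {v} times out of order or beyond horizon")
            for c in kids[v]:
                if self.birth_time[c] != self.end_time[v]:
                    raise ValueError(f"child {c} birth != parent {v} split time")
        if self.flavor == "reconstructed":
            for v in self.leaves():
                if self.end_time[v] != self.t:
                    raise ValueError("reconstructed tree is not ultrametric")


def simulate_complete_tree(
    params: BDParams, t: float, z0: int = 1, seed=None, rng=None
) -> TimedTree:
    """Event-driven simulation of the complete birth-death tree on [0, t].

    The event rate with n extant lineages is n(lam + mu); at each event a
    uniformly chosen lineage splits with probability lam/(lam + mu), else dies.
    Extinct trees are valid outputs (zero extant leaves).
    """
    if t <= 0:
        raise ValueError("t must be > 0")
    if z0 < 1:
        raise ValueError("z0 must be >= 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    lam, mu = params.birth_rate, params.death_rate
    total = lam + mu
    p_split = lam / total

    tree = TimedTree(t=t, flavor="complete")
    for k in range(z0):
        tree.add_node(-1, 0.0, label=k + 1)
    extant = list(range(z0))
    next_label = z0 + 1
    now = 0.0
    while extant:
        now += rng.exponential(1.0 / (total * len(extant)))
        if now >= t:
            break
        i = rng.integers(len(extant))
        v = extant[i]
        # swap-pop keeps the extant list O(1) per event
        extant[i] = extant[-1]
        extant.pop()
        tree.end_time[v] = now
        if rng.random() < p_split:
            tree.end_reason[v] = _SPLIT
            extant.append(tree.add_node(v, now, label=tree.label[v]))
            extant.append(tree.add_node(v, now, label=next_label))
            next_label += 1
        else:
            tree.end_reason[v] = _DEATH
    for v in extant:
        tree.end_time[v] = t
        tree.end_reason[v] = _OBSERVED
    return tree


def reduce_to_leaves(tree: TimedTree, leaf_ids) -> TimedTree | None:
    """Ancestral tree of a subset of leaves, with unary nodes suppressed.

    A split where only one side leads to a kept leaf becomes a pass-through:
    its two branch segments are concatenated and the division is recorded in
    ``divisions``.  The stem from time 0 down to the first kept split is
    retained, so the reduced root still starts at the origin.  Returns None
    for an empty leaf set.
    """
    leaf_ids = list(leaf_ids)
    if not leaf_ids:
        return None
    keep = [False] * len(tree)
    for v in leaf_ids:
        while v >= 0 and not keep[v]:
            keep[v] = True
            v = tree.parent[v]
    kids = tree.children()

    out = TimedTree(t=tree.t, flavor="reconstructed")
    roots = [v for v, p in enumerate(tree.parent) if p == -1 and keep[v]]
    # (original node, reduced parent, birth time of the reduced branch,
    #  divisions at the top of the branch: 1 unless it is the stem)
    stack = [(r, -1, tree.birth_time[r], 0) for r in roots]
    while stack:
        v, new_parent, chain_birth, divs = stack.pop()
        surviving = [c for c in kids[v] if keep[c]]
        while len(surviving) == 1:  # unary: merge branch segments
            divs += 1
            v = surviving[0]
            surviving = [c for c in kids[v] if keep[c]]
        w = out.add_node(new_parent, chain_birth, label=tree.label[v] if not surviving else None)
        out.end_time[w] = tree.end_time[v]
        out.end_reason[w] = _OBSERVED if not surviving else _SPLIT
        out.divisions.append(divs)
        for c in reversed(surviving):
            stack.append((c, w, tree.end_time[v], 1))
    return out


def prune_to_reconstructed(tree: TimedTree) -> TimedTree | None:
    """Drop lineages with no descendant alive at t and suppress unary nodes.

    Returns None for a fully extinct tree; otherwise the reconstructed tree of
    the extant individuals, ultrametric with leaves at the horizon.
    """
    if tree.flavor != "complete":
        raise ValueError("can only prune a complete tree")
    return reduce_to_leaves(tree, tree.leaves())


def sample_yule_split_times(n: int, t: float, lam: float, seed=None, rng=None) -> np.ndarray:
    """Split times of a Yule tree conditioned on n tips at time t.

    The n-1 split times are the increasing order statistics of i.i.d. draws
    from g(u) = lam e^{-lam(t-u)} / (1 - e^{-lam t}), sampled by the explicit
    transform S = log(e^{lam t} V + (1 - V)) / lam of uniforms V.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if t <= 0 or lam <= 0:
        raise ValueError("t and lam must be > 0")
    rng = np.random.default_rng(seed) if rng is None else rng
    v = rng.random(n - 1)
    s = np.log1p(np.expm1(lam * t) * v) / lam
    s.sort()
    return s


def reconstructed_split_cdf(u, t: float, params: BDParams):
    """CDF G(u) = 1 - beta(t-u)/beta(t) of a single split time, 0 <= u <= t."""
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0) or np.any(u_arr > t):
        raise ValueError("u must lie in [0, t]")
    bt, _ = beta_alpha(t, params)
    vals = np.array([beta_alpha(t - ui, params)[0] for ui in np.atleast_1d(u_arr)])
    out = 1.0 - vals / bt
    return out.reshape(u_arr.shape) if u_arr.ndim else float(out[0])


def _beta_inverse(b: float, params: BDParams) -> float:
    """Solve beta(s) = b for s, in closed form."""
    lam, mu = params.birth_rate, params.death_rate
    if b <= 0.0:
        return 0.0
    if params.is_critical:
        return b / (lam * (1.0 - b))
    return math.log((lam - b * mu) / (lam * (1.0 - b))) / (lam - mu)


def reconstructed_split_ppf(q, t: float, params: BDParams):
    """Inverse of reconstructed_split_cdf (probability integral transform)."""
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q_arr < 0) or np.any(q_arr > 1):
        raise ValueError("q must lie in [0, 1]")
    bt, _ = beta_alpha(t, params)
    out = np.array(
        [0.0 if qi == 0.0 else t - _beta_inverse(bt * (1.0 - qi), params) for qi in q_arr]
    )
    return out.reshape(np.shape(q)) if np.ndim(q) else float(out[0])


def simulate_reconstructed_tree(
    n: int, t: float, params: BDParams, seed=None, rng=None
) -> TimedTree:
    """Sample the reconstructed tree of n survivors at time t directly.

    Split times are inverse-CDF transforms of n-1 uniforms through G; given the
    times, the topology grows by bifurcating a uniformly chosen extant lineage
    at each split.  The output is ultrametric with n leaves at depth t and
    keeps the stem from time 0 to the first split.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if t <= 0:
        raise ValueError("t must be > 0")
    rng = np.random.default_rng(seed) if rng is None else rng
    u = reconstructed_split_ppf(rng.random(n - 1), t, params)
    u = np.sort(np.asarray(u))
    # float-resolution ties have probability zero; nudge the later one up
    for i in range(1, len(u)):
        if u[i] <= u[i - 1]:
            u[i] = np.nextafter(u[i - 1], np.inf)
            warnings.warn("split-time tie at float resolution; perturbed by one ulp")

    tree = TimedTree(t=t, flavor="reconstructed")
    tree.add_node(-1, 0.0, label=1)
    extant = [0]
    next_label = 2
    for ui in u:
        i = rng.integers(len(extant))
        v = extant[i]
        extant[i] = extant[-1]
        extant.pop()
        tree.end_time[v] = float(ui)
        tree.end_reason[v] = _SPLIT
        extant.append(tree.add_node(v, float(ui), label=tree.label[v]))
        extant.append(tree.add_node(v, float(ui), label=next_label))
        next_label += 1
    for v in extant:
        tree.end_time[v] = t
        tree.end_reason[v] = _OBSERVED
    return tree
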