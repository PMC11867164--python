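"""Newick and tabular I/O for timed trees.

Dialect: single-line Newick, semicolon-terminated, branch lengths mandatory
and equal to branch *durations* in model time units; the root edge carries the
stem length.  Absolute times are reconstructed on read with the root placed at
time 0.  Trees must be strictly binary.  Node ordering on write follows
creation id, so identical trees serialize identically.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import dendropy

from .tree_sim import TimedTree

__all__ = ["write_newick", "newick_string", "read_newick", "FLOAT_FORMAT"]

# 12 significant digits for all serialized floats
FLOAT_FORMAT = ".12g"

_SPLIT, _DEATH, _OBSERVED = "split", "death", "observed"


def _to_dendropy(tree: TimedTree) -> dendropy.Tree:
    roots = [v for v, p in enumerate(tree.parent) if p == -1]
    if len(roots) != 1:
        raise ValueError(f"Newick needs a single root, tree has {len(roots)}")
    kids = tree.children()
    dt = dendropy.Tree()
    ns = dt.taxon_namespace
    node_map = {}
    for v in range(len(tree)):  # creation order; parents precede children
        if tree.parent[v] == -1:
            nd = dt.seed_node
        else:
            nd = dendropy.Node()
            node_map[tree.parent[v]].add_child(nd)
        node_map[v] = nd
        nd.edge.length = tree.end_time[v] - tree.birth_time[v]
        if not kids[v]:
            lbl = tree.label[v]
            nd.taxon = ns.new_taxon(str(lbl) if lbl is not None else f"n{v}")
    return dt


def newick_string(tree: TimedTree) -> str:
    """Serialize a TimedTree to a one-line Newick string."""
    dt = _to_dendropy(tree)
    s = dt.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=FLOAT_FORMAT,
    ).strip()
    return s + "\n"


def write_newick(tree: TimedTree, path) -> None:
    """Write a TimedTree to a Newick file (see module docstring for the dialect)."""
    Path(path).write_text(newick_string(tree))


def read_newick(source) -> TimedTree:
    """Read a Newick file or string back into a TimedTree.

    Times are reconstructed from the root at time 0; the observation horizon t
    is the maximum tip time, tips at t are marked observed (others dead).
    Polytomies and missing branch lengths are rejected.
    """
    text = str(source)
    try:
        if Path(text).exists():
            text = Path(text).read_text()
    except OSError:  # not a path (e.g. a long Newick string)
        pass
    dt = dendropy.Tree.get(file=_io.StringIO(text), schema="newick")

    # traverse, checking arity and lengths
    tree = TimedTree(t=0.0, flavor="complete")
    root = dt.seed_node
    stem = root.edge.length if root.edge.length is not None else 0.0
    stack = [(root, -1, 0.0, stem)]
    tip_ids = []
    while stack:
        nd, parent_id, birth, length = stack.pop()
        if length is None:
            raise ValueError(f"missing branch length at node {nd}")
        kids = nd.child_nodes()
        if len(kids) not in (0, 2):
            name = nd.taxon.label if nd.taxon else str(nd)
            raise ValueError(f"non-binary node ({len(kids)} children) at {name}")
        label = None
        if nd.taxon is not None:
            try:
                label = int(nd.taxon.label)
            except (TypeError, ValueError):
                label = nd.taxon.label
        v = tree.add_node(parent_id, birth, label=label)
        tree.end_time[v] = birth + length
        tree.end_reason[v] = _SPLIT if kids else _OBSERVED
        if not kids:
            tip_ids.append(v)
        for c in reversed(kids):
            stack.append((c, v, birth + length, c.edge.length))

    t = max(tree.end_time[v] for v in tip_ids)
    tree.t = t
    ultrametric = True
    for v in tip_ids:
        if abs(tree.end_time[v] - t) <= 1e-9 * max(t, 1.0):
            tree.end_time[v] = t
            tree.end_reason[v] = _OBSERVED
        else:
            tree.end_reason[v] = _DEATH
            ultrametric = False
    tree.flavor = "reconstructed" if ultrametric else "complete"
    return tree
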