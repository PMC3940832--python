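"""Neighbor-joining trees with column-resampling bootstrap support.

The distance tree here is a display of the pairwise-divergence structure:
the actual species-delimitation inference is carried by the threshold
grouping in :mod:`moabarcode.delimitation`. Neighbor joining is run on the
K2P matrix; support values come from resampling the kept alignment columns
with replacement, recomputing the matrix and tree, and counting how often
each original bipartition reappears.

Determinism: ties in the NJ selection criterion are broken by the lowest
pair of node creation indices, and each bootstrap replicate draws from its
own stream spawned from the user seed (streams are indexed by replicate,
not by sample), so supports do not depend on sample order beyond genuine
resampling noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from moabarcode.distances import DistanceMatrix, SaturationError, complete_deletion_mask
from moabarcode.seqio import Alignment

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class TreeError(ValueError):
    """Tree construction failed (e.g. undefined distances)."""


@dataclass
class Node:
    """A node in a rooted representation of the (unrooted) NJ tree."""

    name: Optional[str] = None  # leaf name; None for internal nodes
    children: list["Node"] = field(default_factory=list)
    branch_length: float = 0.0  # length of the edge to the parent

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """Unrooted binary tree stored with a trifurcating root.

    ``support`` maps canonical bipartitions (see :func:`bipartitions`) to
    percentages in [0, 100]; ``n_clamped`` counts negative NJ branch-length
    estimates that were clamped to zero.
    """

    root: Node
    support: dict[frozenset[str], float] = field(default_factory=dict)
    n_clamped: int = 0

    @property
    def leaf_names(self) -> list[str]:
        return self.root.leaves()


def _canonical_side(side: frozenset[str], all_leaves: frozenset[str]) -> frozenset[str]:
    # canonical representative: the side NOT containing the smallest leaf name
    anchor = min(all_leaves)
    return all_leaves - side if anchor in side else side


def bipartitions(tree: Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions induced by internal edges, canonicalised."""
    all_leaves = frozenset(tree.leaf_names)
    out: set[frozenset[str]] = set()

    def walk(node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree.root and 1 < len(below) < len(all_leaves) - 1:
            out.add(_canonical_side(below, all_leaves))
        return below

    walk(tree.root)
    return out


def _nj_from_array(d: np.ndarray, names: tuple[str, ...]) -> tuple[Node, int]:
    """Core NJ agglomeration on a dense matrix; returns (root, n_clamped).

    Rows are kept in node-creation order, so ``argmin`` over the selection
    criterion (row-major, first occurrence) realises the documented
    lowest-creation-index tie-break.
    """
    d = d.astype(float).copy()
    nodes: list[Node] = [Node(name=s) for s in names]
    n_clamped = 0
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        Q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), m)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            li, n_clamped = 0.0, n_clamped + 1
        if lj < 0:
            lj, n_clamped = 0.0, n_clamped + 1
        nodes[i].branch_length = li
        nodes[j].branch_length = lj
        new = Node(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (d[i] + d[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.pad(d[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [new]
    # three-point closed form for the final star join
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, l in zip(nodes, (la, lb, lc)):
        if l < 0:
            l, n_clamped = 0.0, n_clamped + 1
        node.branch_length = l
    return Node(children=list(nodes)), n_clamped


def nj_tree(D: DistanceMatrix) -> Tree:
    """Standard neighbor joining, deterministic given input order.

    Requires >= 3 samples and no undefined distances. Negative branch-length
    estimates are clamped to 0 and counted in ``Tree.n_clamped``.
    """
    if D.n < 3:
        raise TreeError("neighbor joining needs at least 3 samples")
    if D.undefined_pairs():
        raise TreeError(f"undefined distances: {D.undefined_pairs()}")
    root, n_clamped = _nj_from_array(D.d, D.sample_ids)
    return Tree(root=root, n_clamped=n_clamped)


def _k2p_from_codes(codes: np.ndarray) -> np.ndarray:
    """Pairwise K2P matrix from an (n, L) array of 0..3 base codes.

    Raises :class:`SaturationError` if any pair is outside the formula's
    domain. With codes A=0, C=1, G=2, T=3 a difference is a transition
    exactly when the codes XOR to 2.
    """
    n, L = codes.shape
    d = np.zeros((n, n))
    for i in range(n):
        xi = codes[i]
        for j in range(i + 1, n):
            xj = codes[j]
            diff = xi != xj
            ts = int(np.count_nonzero(diff & ((xi ^ xj) == 2)))
            tv = int(np.count_nonzero(diff)) - ts
            P, Q = ts / L, tv / L
            w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
            if w1 <= 0 or w2 <= 0:
                raise SaturationError(f"saturated pair ({i}, {j})")
            d[i, j] = d[j, i] = 0.0 if ts == tv == 0 else -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return d


def bootstrap_support(
    alignment: Alignment,
    replicates: int = 500,
    seed: int = 0,
    deletion: str = "complete",
) -> dict[frozenset[str], float]:
    """Bootstrap proportions for each bipartition of the full-data NJ tree.

    Columns kept by the complete-deletion mask are resampled with
    replacement; each replicate recomputes the K2P matrix and NJ tree.
    Replicates containing a saturated (undefined) pair are skipped and
    excluded from the denominator.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    from moabarcode.distances import distance_matrix  # local import avoids a cycle

    D = distance_matrix(alignment, deletion=deletion)
    ref_tree = nj_tree(D)
    targets = bipartitions(ref_tree)
    counts = {b: 0 for b in targets}

    mask = D.mask if D.mask is not None else complete_deletion_mask(alignment)
    cols = np.asarray(mask.kept_columns) - 1
    ids = tuple(alignment.sample_ids)
    codes = np.array(
        [[_CODE[c] for c in (np.asarray(list(seq))[cols])] for seq in alignment.sequences],
        dtype=np.uint8,
    )
    n_cols = codes.shape[1]
    streams = np.random.SeedSequence(seed).spawn(replicates)
    n_ok = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        picked = rng.integers(0, n_cols, size=n_cols)
        try:
            d = _k2p_from_codes(codes[:, picked])
        except SaturationError:
            continue
        n_ok += 1
        root, _ = _nj_from_array(d, ids)
        rep_bips = bipartitions(Tree(root=root))
        for b in targets:
            if b in rep_bips:
                counts[b] += 1
    if n_ok == 0:
        raise TreeError("all bootstrap replicates failed")
    return {b: 100.0 * c / n_ok for b, c in counts.items()}


def _newick(node: Node, tree: Tree, all_leaves: frozenset[str]) -> str:
    if node.is_leaf:
        return f"{node.name}:{node.branch_length:.6f}"
    inner = ",".join(_newick(c, tree, all_leaves) for c in node.children)
    label = ""
    if node is not tree.root and tree.support:
        below = frozenset(node.leaves())
        if 1 < len(below) < len(all_leaves) - 1:
            key = _canonical_side(below, all_leaves)
            if key in tree.support:
                label = str(round(tree.support[key]))
    if node is tree.root:
        return f"({inner}){label}"
    return f"({inner}){label}:{node.branch_length:.6f}"


def to_newick(tree: Tree) -> str:
    """Newick string with branch lengths and integer support labels."""
    return _newick(tree.root, tree, frozenset(tree.leaf_names)) + ";"


def write_newick(tree: Tree, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")
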