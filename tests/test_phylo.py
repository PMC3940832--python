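import itertools

import dendropy
import numpy as np
import pytest

from moabarcode.distances import DistanceMatrix, distance_matrix
from moabarcode.phylo import (
    Node,
    Tree,
    TreeError,
    _canonical_side,
    bipartitions,
    bootstrap_support,
    nj_tree,
    to_newick,
    write_newick,
)
from moabarcode.seqio import Alignment
from moabarcode.synthetic_data import simulate_alignment, symmetric_population_config


def dmatrix(ids, d):
    return DistanceMatrix(tuple(ids), np.asarray(d, dtype=float), None)


def random_binary_tree(rng, names):
    """Random unrooted binary tree as nested Nodes with uniform lengths."""
    nodes = [Node(name=n, branch_length=float(rng.uniform(0.5, 3.0))) for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        rest = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        parent = Node(children=[b, a], branch_length=float(rng.uniform(0.5, 3.0)))
        nodes = rest + [parent]
    return Tree(root=Node(children=nodes))


def path_lengths(tree):
    """All-pairs leaf path lengths by accumulating branch lengths."""
    dists = {}

    # distances via lowest common ancestor: combine child subtree maps
    def collect(node):
        if node.is_leaf:
            return {node.name: 0.0}
        maps = []
        for c in node.children:
            m = collect(c)
            maps.append({k: v + c.branch_length for k, v in m.items()})
        for m1, m2 in itertools.combinations(maps, 2):
            for a, da in m1.items():
                for b, db in m2.items():
                    dists[frozenset((a, b))] = da + db
        merged = {}
        for m in maps:
            merged.update(m)
        return merged

    collect(tree.root)
    return dists


def additive_matrix(tree):
    names = sorted(tree.leaf_names)
    pl = path_lengths(tree)
    n = len(names)
    d = np.zeros((n, n))
    for i, a in enumerate(names):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pl[frozenset((a, names[j]))]
    return DistanceMatrix(tuple(names), d, None)


def dendropy_bipartitions(newick, leaf_names):
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.encode_bipartitions()
    all_leaves = frozenset(leaf_names)
    out = set()
    for edge in t.preorder_edge_iter():
        if edge.head_node is t.seed_node or edge.head_node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in edge.head_node.leaf_iter())
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(_canonical_side(side, all_leaves))
    return out


class TestNJ:
    def test_three_taxa_closed_form(self):
        D = dmatrix(["a", "b", "c"], [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        t = nj_tree(D)
        lengths = {c.name: c.branch_length for c in t.root.children}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_four_taxa_additive_recovery(self):
        # hand-drawn tree: ((a:1,b:2):3,c:4,d:5) with internal edge 3
        d = [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]]
        t = nj_tree(dmatrix(["a", "b", "c", "d"], d))
        assert bipartitions(t) == {frozenset({"c", "d"})}
        pl = path_lengths(t)
        assert pl[frozenset(("a", "b"))] == pytest.approx(3.0)
        assert pl[frozenset(("b", "d"))] == pytest.approx(10.0)

    @pytest.mark.parametrize("n_taxa", [6, 8])
    def test_additive_recovery_random_trees(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(10):
            truth = random_binary_tree(rng, [f"t{i}" for i in range(n_taxa)])
            D = additive_matrix(truth)
            est = nj_tree(D)
            assert bipartitions(est) == bipartitions(truth)
            true_pl = path_lengths(truth)
            est_pl = path_lengths(est)
            for pair, v in true_pl.items():
                assert est_pl[pair] == pytest.approx(v, abs=1e-9)

    def test_matches_scikit_bio_topology(self):
        import skbio

        rng = np.random.default_rng(17)
        truth = random_binary_tree(rng, [f"t{i}" for i in range(7)])
        D = additive_matrix(truth)
        est = nj_tree(D)
        sk = skbio.tree.nj(skbio.DistanceMatrix(D.d, ids=list(D.sample_ids)))
        sk_bips = dendropy_bipartitions(str(sk).strip(), D.sample_ids)
        assert bipartitions(est) == sk_bips

    def test_identical_sequences_give_zero_length_cherry(self):
        seqs = {"a": "ACGTACGTAC", "b": "ACGTACGTAC", "c": "ACGTACGAAC", "d": "ACTTACGAAC", "e": "GCTTACGAAG"}
        aln = Alignment(tuple(seqs.items()))
        t = nj_tree(distance_matrix(aln))
        pl = path_lengths(t)
        assert pl[frozenset(("a", "b"))] == pytest.approx(0.0, abs=1e-12)

    def test_undefined_distance_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(TreeError):
            nj_tree(dmatrix(["a", "b", "c"], d))


class TestNewick:
    def test_three_taxon_single_line(self):
        t = nj_tree(dmatrix(["a", "b", "c"], [[0, 3, 4], [3, 0, 5], [4, 5, 0]]))
        s = to_newick(t)
        assert s.endswith(";") and "\n" not in s

    def test_round_trip_preserves_topology(self, tmp_path):
        rng = np.random.default_rng(3)
        truth = random_binary_tree(rng, [f"t{i}" for i in range(6)])
        est = nj_tree(additive_matrix(truth))
        path = tmp_path / "t.nwk"
        write_newick(est, path)
        assert dendropy_bipartitions(path.read_text(), est.leaf_names) == bipartitions(est)

    def test_support_labels_written(self):
        t = nj_tree(dmatrix(["a", "b", "c", "d"], [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]]))
        t.support = {frozenset({"c", "d"}): 97.0}
        assert ")97:" in to_newick(t)


class TestBootstrap:
    def test_separated_populations_high_support(self):
        cfg = symmetric_population_config(
            intra=0.003, inter=0.02, n=6, populations=("FarNorth", "FarSouth"), seed=0
        )
        aln, pops = simulate_alignment(cfg)
        sup = bootstrap_support(aln, replicates=100, seed=1)
        side = frozenset(s for s, p in pops.items() if p == "FarSouth")
        key = _canonical_side(side, frozenset(aln.sample_ids))
        assert sup[key] >= 95.0

    def test_single_replicate_gives_zero_or_hundred(self):
        cfg = symmetric_population_config(intra=0.004, inter=0.02, n=4,
                                          populations=("FarNorth", "FarSouth"), seed=2)
        aln, _ = simulate_alignment(cfg)
        sup = bootstrap_support(aln, replicates=1, seed=3)
        assert set(sup.values()) <= {0.0, 100.0}

    def test_structureless_data_has_weak_internal_support(self):
        # star-like truth: all inter-sample divergences equal in expectation
        cfg = symmetric_population_config(intra=0.01, inter=0.01, n=4, seed=4)
        aln, _ = simulate_alignment(cfg)
        sup = bootstrap_support(aln, replicates=100, seed=5)
        assert np.mean(list(sup.values())) < 90.0

    def test_support_invariant_to_sample_order(self):
        cfg = symmetric_population_config(
            intra=0.003, inter=0.02, n=5, populations=("FarNorth", "FarSouth"), seed=6
        )
        aln, pops = simulate_alignment(cfg)
        rev = Alignment(tuple(reversed(aln.records)), aln.ref_start, aln.ref_name)
        side = frozenset(s for s, p in pops.items() if p == "FarSouth")
        key = _canonical_side(side, frozenset(aln.sample_ids))
        s1 = bootstrap_support(aln, replicates=50, seed=7)[key]
        s2 = bootstrap_support(rev, replicates=50, seed=7)[key]
        assert s1 == s2
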