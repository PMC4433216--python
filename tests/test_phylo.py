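"""Neighbor joining, bootstrap and Newick round trips.

The NJ consistency oracle builds random additive matrices from random
binary topologies (leaf-leaf path lengths) independently of the tree code
under test; NJ must recover each generating topology exactly.
"""

import numpy as np
import pytest

from herbcode.distances import DistanceMatrix, matrix_from_codes
from herbcode.phylo import (
    BootstrapResult,
    UndefinedDistanceError,
    _bipartitions,
    bootstrap_support,
    nj_tree,
    read_newick,
    rf_distance,
    write_newick,
)
from herbcode.seqstore import MarkerSequence, build_aligned_set
from herbcode.simulate import evolve


# --- independent oracle: random additive trees ------------------------------


class _Node:
    def __init__(self, label=None):
        self.label = label
        self.children = []  # (child, branch length)


def random_additive_tree(n_leaves: int, rng) -> tuple[_Node, list[str]]:
    """Random binary topology grown by leaf insertion, random branch lengths."""
    labels = [f"L{i}" for i in range(n_leaves)]
    root = _Node()
    for lab in labels[:3]:
        root.children.append((_Node(lab), float(rng.uniform(0.05, 1.0))))
    for lab in labels[3:]:
        es = _collect_edges(root)
        parent, idx = es[rng.integers(0, len(es))]
        child, length = parent.children[idx]
        split = float(rng.uniform(0.2, 0.8))
        mid = _Node()
        mid.children.append((child, length * (1 - split)))
        mid.children.append((_Node(lab), float(rng.uniform(0.05, 1.0))))
        parent.children[idx] = (mid, length * split)
    return root, labels


def _collect_edges(node):
    out = []
    for idx, (child, _) in enumerate(node.children):
        out.append((node, idx))
        out.extend(_collect_edges(child))
    return out


def _leaf_depths(node, depth, acc):
    if node.label is not None:
        acc[node.label] = (depth, node)
    for child, length in node.children:
        _leaf_depths(child, depth + length, acc)


def tree_to_matrix(root, labels) -> DistanceMatrix:
    # path lengths via LCA over recorded root-to-leaf paths
    paths = {}

    def walk(node, path):
        if node.label is not None:
            paths[node.label] = path
        for idx, (child, length) in enumerate(node.children):
            walk(child, path + [(id(node), idx, length)])

    walk(root, [])
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = paths[labels[i]], paths[labels[j]]
            k = 0
            while k < min(len(pi), len(pj)) and pi[k][:2] == pj[k][:2]:
                k += 1
            d = sum(l for *_, l in pi[k:]) + sum(l for *_, l in pj[k:])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values, "p", 1)


def oracle_bipartitions(root, labels) -> set[frozenset]:
    all_set = frozenset(labels)
    ref = min(labels)
    out = set()

    def leaves_under(node):
        if node.label is not None:
            return {node.label}
        s = set()
        for child, _ in node.children:
            s |= leaves_under(child)
        return s

    def walk(node):
        for child, _ in node.children:
            side = frozenset(leaves_under(child))
            if ref in side:
                side = all_set - side
            if 1 < len(side) < len(all_set) - 1:
                out.add(side)
            walk(child)

    walk(root)
    return out


# --- tests ------------------------------------------------------------------


class TestNJ:
    def test_quartet_recovers_split_and_internal_length(self):
        # additive quartet ((A:1,B:1):1,(C:1,D:1)): internal branch length 1
        labels = ["A", "B", "C", "D"]
        values = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], dtype=float
        )
        tree = nj_tree(DistanceMatrix(labels, values, "p", 1))
        assert _bipartitions(tree) == {frozenset({"C", "D"})}
        internal = [
            node.edge.length
            for node in tree.preorder_node_iter()
            if node is not tree.seed_node and not node.is_leaf()
        ]
        assert internal == [pytest.approx(1.0)]

    def test_three_taxa_closed_form(self):
        labels = ["a", "b", "c"]
        values = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(labels, values, "p", 1))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        # b(i) = (d(i,j) + d(i,k) - d(j,k)) / 2
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_row_permutation_leaves_topology_unchanged(self, rng):
        root, labels = random_additive_tree(7, rng)
        dm = tree_to_matrix(root, labels)
        t1 = nj_tree(dm)
        perm = list(rng.permutation(len(labels)))
        dm2 = DistanceMatrix(
            [labels[i] for i in perm], dm.values[np.ix_(perm, perm)], "p", 1
        )
        t2 = nj_tree(dm2)
        assert rf_distance(t1, t2) == 0

    def test_additive_consistency_small_batch(self, rng):
        for _ in range(10):
            root, labels = random_additive_tree(8, rng)
            tree = nj_tree(tree_to_matrix(root, labels))
            assert _bipartitions(tree) == oracle_bipartitions(root, labels)

    def test_agrees_with_independent_nj_implementation(self, rng):
        import skbio

        root, labels = random_additive_tree(8, rng)
        dm = tree_to_matrix(root, labels)
        ours = nj_tree(dm)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(dm.values, ids=labels))
        their_bips = set()
        all_set = frozenset(labels)
        ref = min(labels)
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = all_set - side
            if 1 < len(side) < len(all_set) - 1:
                their_bips.add(side)
        assert _bipartitions(ours) == their_bips

    def test_refuses_undefined_entries_and_tiny_matrices(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)), "K2P", 1,
                            undefined_pairs=[("a", "b")])
        with pytest.raises(UndefinedDistanceError):
            nj_tree(dm)
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2)), "p", 1))


class TestNewickAndRF:
    def test_round_trip_topology_lengths_supports(self, rng):
        root, labels = random_additive_tree(6, rng)
        tree = nj_tree(tree_to_matrix(root, labels))
        for node in tree.preorder_node_iter():
            if node is not tree.seed_node and not node.is_leaf():
                node.label = "87"
        text = write_newick(tree)
        back = read_newick(text)
        assert rf_distance(tree, back) == 0
        ours = sorted(
            round(n.edge.length, 6) for n in tree.preorder_node_iter()
            if n.edge.length is not None
        )
        theirs = sorted(
            round(n.edge.length, 6) for n in back.preorder_node_iter()
            if n.edge.length is not None
        )
        assert ours == theirs
        assert "87" in text

    def test_rf_of_tree_with_itself_is_zero(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert rf_distance(t, t) == 0

    def test_conflicting_quartets_have_rf_two(self):
        t1 = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = read_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert rf_distance(t1, t2) == 2

    def test_malformed_newick_rejected(self):
        with pytest.raises(ValueError, match="Newick"):
            read_newick("((A,B,(C;")


def _two_clade_alignment(between: float = 0.10, n_per_clade: int = 3, L: int = 500):
    rng = np.random.default_rng(99)
    rootA = rng.integers(0, 4, L).astype(np.uint8)
    rootB = evolve(rootA, between, 2.0, rng)
    from herbcode.seqstore import decode_bases

    seqs = []
    for i in range(n_per_clade):
        seqs.append(MarkerSequence(f"A{i}", "matK", decode_bases(rootA),
                                   role="reference", species_label="Clade a"))
    for i in range(n_per_clade):
        seqs.append(MarkerSequence(f"B{i}", "matK", decode_bases(rootB),
                                   role="reference", species_label="Clade b"))
    return build_aligned_set(seqs)


class TestBootstrap:
    def test_clean_two_clade_signal_gets_full_support(self):
        aset = _two_clade_alignment()
        res = bootstrap_support(aset, n_reps=100, seed=5)
        assert res.supports  # non-trivial internal edges exist
        assert all(v == 100.0 for v in res.supports.values())
        assert res.n_failed == 0

    def test_single_replicate_supports_are_zero_or_hundred(self):
        aset = _two_clade_alignment()
        res = bootstrap_support(aset, n_reps=1, seed=1)
        assert set(res.supports.values()) <= {0.0, 100.0}

    def test_fixed_seed_reproducible(self):
        aset = _two_clade_alignment()
        r1 = bootstrap_support(aset, n_reps=25, seed=42)
        r2 = bootstrap_support(aset, n_reps=25, seed=42)
        assert r1.supports == r2.supports

    def test_support_increases_with_signal(self):
        # monotone non-decreasing support along a divergence gradient
        sups = []
        for between in (0.002, 0.01, 0.08):
            aset = _two_clade_alignment(between=between)
            res = bootstrap_support(aset, n_reps=50, seed=3)
            central = [v for bp, v in res.supports.items() if len(bp) == 3]
            sups.append(max(central) if central else 0.0)
        assert sups == sorted(sups)
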