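"""Hamming distances, neighbor joining, Newick round trips.

The NJ oracle is twofold: brute-force enumeration of all 15 unrooted
5-leaf topologies with a least-squares branch-length fit (the generating
topology is the unique one with zero residual on an additive matrix), and
scikit-bio's independent NJ implementation.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.optimize import nnls
from skbio import DistanceMatrix as SkDistanceMatrix
from skbio import TreeNode
from skbio.tree import nj as skbio_nj

from imaclone.clonality import build_presence_matrix
from imaclone.phylo import (
    DistanceMatrix,
    hamming_distance_matrix,
    neighbor_joining,
    read_newick,
    to_newick,
)
from tests.test_clonality import matrix_from


# ---------------------------------------------------------------------------
# brute-force topology oracle
# ---------------------------------------------------------------------------


def enumerate_unrooted_topologies(labels):
    """All unrooted binary topologies as edge lists, by edge insertion."""
    a, b, c = labels[:3]
    center = "I0"
    trees = [[(a, center), (b, center), (c, center)]]
    for k, leaf in enumerate(labels[3:], start=1):
        new_trees = []
        node = f"I{k}"
        for edges in trees:
            for i, (u, v) in enumerate(edges):
                rest = edges[:i] + edges[i + 1 :]
                new_trees.append(rest + [(u, node), (v, node), (leaf, node)])
        trees = new_trees
    return trees


def ls_residual(edges, labels, d):
    """Least-squares (non-negative) branch-length fit residual of a topology."""
    import networkx as nx

    g = nx.Graph(edges)
    edge_list = list(g.edges)
    pairs = list(itertools.combinations(labels, 2))
    A = np.zeros((len(pairs), len(edge_list)))
    y = np.zeros(len(pairs))
    for r, (u, v) in enumerate(pairs):
        path = nx.shortest_path(g, u, v)
        for s, t in zip(path, path[1:]):
            for ei, (eu, ev) in enumerate(edge_list):
                if {s, t} == {eu, ev}:
                    A[r, ei] = 1
        y[r] = d[labels.index(u), labels.index(v)]
    _, res = nnls(A, y)
    return res


def splits_of(edges, labels):
    """Non-trivial bipartitions induced by a topology's internal edges."""
    import networkx as nx

    g = nx.Graph(edges)
    leaves = set(labels)
    out = set()
    for u, v in list(g.edges):
        h = g.copy()
        h.remove_edge(u, v)
        comp = set(nx.node_connected_component(h, u)) & leaves
        sides = sorted((comp, leaves - comp), key=lambda s: (len(s), sorted(s)))
        side = sides[0]
        if 1 < len(side) < len(leaves) - 1:
            out.add(frozenset(side))
    return out


def tree_splits(tree, labels):
    """Canonical non-trivial bipartitions of a scikit-bio tree."""
    for i, n in enumerate(tree.traverse(include_self=True)):
        if n.name is None:
            n.name = f"_I{i}"
    edges = [
        (n.name, c.name) for n in tree.traverse(include_self=True) for c in n.children
    ]
    return splits_of(edges, labels)


def random_additive(labels, rng):
    """Random binary tree over labels with random lengths; return (tree, D)."""
    items = [TreeNode(name=lab) for lab in labels]
    for node in items:
        node.length = float(rng.uniform(0.5, 3.0))
    while len(items) > 2:
        i, j = sorted(rng.choice(len(items), 2, replace=False))
        parent = TreeNode(children=[items[i], items[j]])
        parent.length = float(rng.uniform(0.5, 3.0))
        items = [x for k, x in enumerate(items) if k not in (i, j)] + [parent]
    tree = TreeNode(children=items)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tree.find(labels[i]).distance(tree.find(labels[j]))
    return tree, d


# ---------------------------------------------------------------------------
# Hamming distances
# ---------------------------------------------------------------------------


class TestHamming:
    def test_hand_examples(self):
        pm = matrix_from([[1, 1, 0], [1, 0, 1], [1, 1, 0]])
        dm = hamming_distance_matrix(pm, include_root=False)
        assert dm.matrix[0, 1] == 2
        assert dm.matrix[0, 2] == 0

    def test_root_distance_is_variant_count(self):
        pm = matrix_from([[1] * 47, [1] * 37 + [0] * 10])
        dm = hamming_distance_matrix(pm, include_root=True)
        assert dm.labels[-1] == "Normal"
        assert dm.matrix[2, 0] == 47
        assert dm.matrix[2, 1] == 37

    @given(
        cells=arrays(np.uint8, (4, 15), elements=st.integers(0, 1)).filter(
            lambda a: (a.sum(axis=0) > 0).all()
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_triangle_inequality(self, cells):
        dm = hamming_distance_matrix(matrix_from(cells), include_root=True)
        m = dm.matrix
        n = len(dm.labels)
        for i, j, k in itertools.permutations(range(n), 3):
            assert m[i, j] <= m[i, k] + m[k, j]

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


class TestNeighborJoining:
    def test_two_taxa(self):
        tree = neighbor_joining(DistanceMatrix(["A", "B"], np.array([[0.0, 5.0], [5.0, 0.0]])))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] + lengths["B"] == pytest.approx(5.0)

    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 2, 4], [2, 0, 4], [4, 4, 0]])
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        dist = {
            (a, b): tree.find(a).distance(tree.find(b))
            for a, b in [("A", "B"), ("A", "C"), ("B", "C")]
        }
        # a=1, b=1, c=3 from the closed form (d_ab+d_ac-d_bc)/2 etc.
        assert dist[("A", "B")] == pytest.approx(2)
        assert dist[("A", "C")] == pytest.approx(4)
        assert dist[("B", "C")] == pytest.approx(4)

    def test_five_taxon_brute_force_oracle(self):
        labels = list("ABCDE")
        rng = np.random.default_rng(5)
        for _ in range(5):
            true_tree, d = random_additive(labels, rng)
            topologies = enumerate_unrooted_topologies(labels)
            assert len(topologies) == 15
            residuals = [ls_residual(e, labels, d) for e in topologies]
            assert sum(r < 1e-6 for r in residuals) == 1  # unique additive fit
            best = topologies[int(np.argmin(residuals))]
            # NJ must recover exactly the topology the brute force singles out
            mine = neighbor_joining(DistanceMatrix(labels, d))
            assert tree_splits(mine, labels) == splits_of(best, labels)
            assert mine.compare_rfd(true_tree, rooted=False) == 0

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_additive_recovery_and_skbio_agreement(self, n_taxa):
        labels = [f"T{i}" for i in range(n_taxa)]
        rng = np.random.default_rng(n_taxa)
        for _ in range(10):
            true_tree, d = random_additive(labels, rng)
            mine = neighbor_joining(DistanceMatrix(labels, d))
            assert mine.compare_rfd(true_tree, rooted=False) == 0
            theirs = skbio_nj(SkDistanceMatrix(d, ids=labels))
            assert mine.compare_rfd(theirs, rooted=False) == 0

    def test_negative_branch_clamped_to_zero(self, tmp_path):
        # triangle-violating distances force a negative length estimate
        d = np.array([[0.0, 2, 2], [2, 0, 5], [2, 5, 0]])
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        assert all(t.length >= 0 for t in tree.traverse() if t.length is not None)
        to_newick(tree, tmp_path / "t.nwk")
        assert "-" not in (tmp_path / "t.nwk").read_text()

    def test_deterministic_tie_break(self):
        d = np.ones((4, 4)) - np.eye(4)  # fully tied Q matrix
        t1 = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        t2 = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        assert str(t1) == str(t2)


class TestNewick:
    def test_round_trip_isomorphism(self, tmp_path):
        rng = np.random.default_rng(1)
        _, d = random_additive(list("ABCDE"), rng)
        tree = neighbor_joining(DistanceMatrix(list("ABCDE"), d))
        to_newick(tree, tmp_path / "t.nwk")
        again = read_newick(tmp_path / "t.nwk")
        assert tree.compare_rfd(again, rooted=False) == 0

    def test_two_leaf_serialization(self, tmp_path):
        tree = neighbor_joining(DistanceMatrix(["A", "B"], np.array([[0.0, 3.0], [3.0, 0.0]])))
        to_newick(tree, tmp_path / "t.nwk")
        text = (tmp_path / "t.nwk").read_text()
        assert "A:3" in text and "B:0" in text
        assert read_newick(tmp_path / "t.nwk").compare_rfd(tree, rooted=False) == 0


def test_simulated_patient_tree_additivity(sim_loaded):
    """With noiseless presence, NJ path distances reproduce Hamming distances
    and the trunk (Normal-side) length is positive iff truncal mutations exist."""
    cohort, truth = sim_loaded
    from imaclone.filtering import apply_filters
    from imaclone.variants import RegionCallset

    for pid in ("SIM01", "SIM07"):
        callsets = []
        for cs in cohort[pid]:
            passing, _ = apply_filters(cs.variants)
            callsets.append(
                RegionCallset(cs.patient_id, cs.region_label, passing, cs.callable_mb)
            )
        pm = build_presence_matrix(callsets)
        dm = hamming_distance_matrix(pm, include_root=True)
        tree = neighbor_joining(dm)
        for i, a in enumerate(dm.labels):
            for j in range(i + 1, len(dm.labels)):
                b = dm.labels[j]
                assert tree.find(a).distance(tree.find(b)) == pytest.approx(
                    dm.matrix[i, j], abs=1e-6
                )
        n_truncal = sum(
            1 for t in truth.patients[pid].variants if t.clone == "trunk"
        )
        normal = tree.find("Normal")
        if n_truncal > 0:
            assert normal.length >= n_truncal  # trunk includes all shared variants
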