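import random

import numpy as np
import pytest

from additive import path_distance_matrix, random_additive_tree, true_edge_bipartitions
from vitisnp.distances import DistanceMatrix, k2p_matrix
from vitisnp.errors import UndefinedDistanceError, VitisnpError
from vitisnp.tree import (
    bootstrap_supports,
    edge_lengths_by_bipartition,
    nj_tree,
    root_on_outgroup,
    tree_bipartitions,
)


class TestNJ:
    def test_three_taxa_closed_form(self):
        # three-point formulas: la=(dab+dac-dbc)/2 etc.
        M = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        t = nj_tree(DistanceMatrix(["A", "B", "C"], M))
        lengths = edge_lengths_by_bipartition(t)
        assert lengths[frozenset({"B", "C"})] == pytest.approx(0.1)  # A: (0.3+0.5-0.6)/2
        assert lengths[frozenset({"B"})] == pytest.approx(0.2)
        assert lengths[frozenset({"C"})] == pytest.approx(0.4)

    def test_additive_four_taxon_exact(self):
        # tree ((A:1,B:2):0.5,(C:3,D:4)) -> additive matrix
        M = np.array(
            [
                [0, 3, 4.5, 5.5],
                [3, 0, 5.5, 6.5],
                [4.5, 5.5, 0, 7],
                [5.5, 6.5, 7, 0],
            ],
            dtype=float,
        )
        t = nj_tree(DistanceMatrix(list("ABCD"), M))
        lengths = edge_lengths_by_bipartition(t)
        assert frozenset({"C", "D"}) in lengths
        assert lengths[frozenset({"C", "D"})] == pytest.approx(0.5)
        # leaf A's edge is keyed by its complement side (A is the reference)
        assert lengths[frozenset({"B", "C", "D"})] == pytest.approx(1.0)
        assert lengths[frozenset({"D"})] == pytest.approx(4.0)

    def test_long_branch_attachment(self):
        # taxon E hangs far from the (C,D) side; check placement against the
        # generating topology
        rng = random.Random(11)
        adj, leaves = random_additive_tree(5, rng)
        # stretch one leaf edge strongly
        lf = leaves[-1]
        (nbr,) = adj[lf]
        adj[lf][nbr] += 10.0
        adj[nbr][lf] += 10.0
        M = path_distance_matrix(adj, leaves)
        t = nj_tree(DistanceMatrix(leaves, M))
        assert tree_bipartitions(t) == {
            k for k in true_edge_bipartitions(adj, leaves) if 2 <= len(k) <= len(leaves) - 2
        }

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(VitisnpError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_undefined_distances_refused(self):
        vals = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(UndefinedDistanceError):
            nj_tree(DistanceMatrix(["a", "b", "c"], vals, [("a", "b")]))

    def test_agrees_with_skbio_on_random_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = random.Random(5)
        adj, leaves = random_additive_tree(7, rng)
        M = path_distance_matrix(adj, leaves)
        # perturb slightly so the matrix is merely near-additive
        noise = np.random.default_rng(0).uniform(0, 0.01, M.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        M2 = M + noise
        M2 = (M2 + M2.T) / 2  # exact float symmetry
        ours = nj_tree(DistanceMatrix(leaves, M2))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(M2, ids=leaves))
        from vitisnp.io import read_newick

        theirs_dp = read_newick(str(theirs))
        assert tree_bipartitions(ours) == tree_bipartitions(theirs_dp)


class TestRooting:
    def test_root_on_outgroup_clade(self):
        rng = random.Random(2)
        adj, leaves = random_additive_tree(6, rng)
        M = path_distance_matrix(adj, leaves)
        t = nj_tree(DistanceMatrix(leaves, M))
        # pick an existing cherry as 'outgroup'
        bip = next(iter(tree_bipartitions(t)))
        og = sorted(bip)
        t = root_on_outgroup(t, og)
        assert t.is_rooted
        kids = t.seed_node.child_nodes()
        sides = [frozenset(lf.taxon.label for lf in k.leaf_iter()) for k in kids]
        assert frozenset(og) in sides

    def test_missing_outgroup_label_rejected(self):
        M = np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0]], dtype=float)
        t = nj_tree(DistanceMatrix(["a", "b", "c"], M))
        with pytest.raises(VitisnpError):
            root_on_outgroup(t, ["zz"])


class TestBootstrap:
    SEQS = {
        "a": "ACGTACGTACGTACGTAAAA",
        "b": "ACGTACGTACGTACGTAAAT",
        "c": "ACGTACGTACGTTCGAAGAT",
        "d": "ACGAACGTACGTTCGAAGGT",
    }

    def test_single_replicate_supports_are_0_or_100(self):
        boot = bootstrap_supports(self.SEQS, 1, seed=0)
        assert set(boot.supports.values()) <= {0.0, 100.0}

    def test_same_seed_identical(self):
        b1 = bootstrap_supports(self.SEQS, 25, seed=42)
        b2 = bootstrap_supports(self.SEQS, 25, seed=42)
        assert b1.supports == b2.supports

    def test_label_permutation_invariance(self):
        order1 = list(self.SEQS)
        order2 = list(reversed(order1))
        b1 = bootstrap_supports(self.SEQS, 30, seed=7, labels=order1)
        b2 = bootstrap_supports(self.SEQS, 30, seed=7, labels=order2)
        assert b1.supports == b2.supports

    def test_too_short_alignment_rejected(self):
        with pytest.raises(VitisnpError):
            bootstrap_supports({"a": "A", "b": "A", "c": "A"}, 5, seed=0)

    def test_integer_support_labels_on_tree(self):
        boot = bootstrap_supports(self.SEQS, 10, seed=3)
        labels = [
            n.label
            for n in boot.tree.preorder_node_iter()
            if n.parent_node is not None and not n.is_leaf()
        ]
        assert all(l is None or l.isdigit() for l in labels)
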