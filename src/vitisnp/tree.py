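"""Neighbor-joining trees and nonparametric bootstrap supports.

NJ follows the Saitou-Nei agglomeration with the rate-corrected Q-criterion
and is exact on additive distance matrices.  Estimated branch lengths that
come out negative are clamped to zero with the deficit transferred to the
sibling edge, so the path length between the joined pair is preserved.

Bootstrap supports resample alignment *columns* with replacement, rebuild
the NJ tree from the K2P matrix of each pseudo-alignment and report, for
every internal bipartition of the point-estimate tree, the percentage of
replicate trees containing that bipartition.  All randomness flows from one
explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np

from .distances import DistanceMatrix, _codes_matrix, k2p_matrix_from_codes, require_defined
from .errors import UndefinedDistanceError, VitisnpError

__all__ = [
    "nj_tree",
    "root_on_outgroup",
    "bootstrap_supports",
    "BootstrapResult",
    "tree_bipartitions",
    "edge_lengths_by_bipartition",
]


def nj_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """Build the (unrooted) neighbor-joining tree for a distance matrix.

    Requires >= 3 labels and fully defined, finite distances.  The returned
    dendropy tree has a trifurcating seed node, i.e. it represents an
    unrooted topology.
    """
    if matrix.n < 3:
        raise VitisnpError("neighbor-joining needs at least 3 taxa")
    require_defined(matrix)
    if not np.isfinite(matrix.values).all():
        raise UndefinedDistanceError("distance matrix contains non-finite entries")

    tns = dendropy.TaxonNamespace(matrix.labels)
    nodes: list[dendropy.Node] = []
    for lab in matrix.labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(node)
    D = matrix.values.astype(float).copy()
    active = list(range(matrix.n))

    def set_edge(parent: dendropy.Node, child_idx: int, length: float) -> None:
        child = nodes[child_idx]
        parent.add_child(child)
        child.edge.length = max(0.0, float(length))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        d_ij = sub[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        # clamp negatives, moving the deficit to the sibling edge
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        gi, gj = active[i], active[j]
        new = dendropy.Node()
        nodes.append(new)
        g_new = len(nodes) - 1
        set_edge(new, gi, li)
        set_edge(new, gj, lj)
        # distances from the new node to every other active node
        rest = [g for g in active if g not in (gi, gj)]
        newrow = np.zeros(len(nodes))
        for g in rest:
            newrow_g = 0.5 * (D[gi, g] + D[gj, g] - d_ij)
            newrow[g] = max(0.0, newrow_g)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[g_new, : g_new] = newrow[: g_new]
        D[: g_new, g_new] = newrow[: g_new]
        active = rest + [g_new]

    # closing three-point step
    ga, gb, gc = active
    d_ab, d_ac, d_bc = D[ga, gb], D[ga, gc], D[gb, gc]
    la = 0.5 * (d_ab + d_ac - d_bc)
    lb = 0.5 * (d_ab + d_bc - d_ac)
    lc = 0.5 * (d_ac + d_bc - d_ab)
    root = dendropy.Node()
    for g, l in ((ga, la), (gb, lb), (gc, lc)):
        nodes_idx = g
        root.add_child(nodes[nodes_idx])
        nodes[nodes_idx].edge.length = max(0.0, float(l))
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (unrooted) tree, each canonicalised as
    the side *not* containing the lexicographically smallest leaf label."""
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = leaves[0]
    all_set = frozenset(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = _leafset(node)
        key = side if ref not in side else all_set - side
        if 2 <= len(key) <= len(leaves) - 2:
            out.add(key)
    return out


def edge_lengths_by_bipartition(tree: dendropy.Tree) -> dict[frozenset[str], float]:
    """Map every edge (leaf and internal) to its length, keyed by the
    canonical bipartition side (the side not containing the reference leaf)."""
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = leaves[0]
    all_set = frozenset(leaves)
    out: dict[frozenset[str], float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = _leafset(node)
        key = side if ref not in side else all_set - side
        out[key] = out.get(key, 0.0) + (node.edge.length or 0.0)
    return out


def root_on_outgroup(tree: dendropy.Tree, outgroup: Sequence[str]) -> dendropy.Tree:
    """Root the tree on the edge separating the outgroup set from the rest.

    If the outgroup is not monophyletic in the unrooted topology, the tree is
    rooted at the edge of the most recent common ancestor of the outgroup
    taxa instead.
    """
    og = frozenset(outgroup)
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    if not og or not og <= leaves:
        raise VitisnpError(f"outgroup labels not all present in tree: {sorted(og - leaves)}")
    target = None
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = _leafset(node)
        if side == og or (leaves - side) == og:
            target = node
            break
    if target is None:
        mrca = tree.mrca(taxon_labels=list(og))
        target = mrca if mrca.parent_node is not None else next(
            iter(mrca.child_nodes())
        )
    length = target.edge.length or 0.0
    tree.reroot_at_edge(target.edge, length1=length / 2.0, length2=length / 2.0)
    tree.is_rooted = True
    return tree


@dataclass
class BootstrapResult:
    tree: dendropy.Tree  # point-estimate tree annotated with integer supports
    supports: dict[frozenset[str], float]  # bipartition -> percent
    n_replicates: int
    n_effective: int  # replicates with fully defined distance matrices


def bootstrap_supports(
    sequences: Mapping[str, str],
    n_reps: int,
    seed: int,
    labels: Optional[Sequence[str]] = None,
) -> BootstrapResult:
    """Column-resampling bootstrap of the NJ/K2P tree.

    ``sequences`` is the concatenated aligned consensus per accession.  All
    alignment columns are resampled (monomorphic ones included), keeping
    resampling proportions honest.  Replicates whose K2P matrix contains an
    undefined distance are skipped and excluded from the support denominator;
    ``n_effective`` reports how many replicates were used.
    """
    if n_reps < 1:
        raise VitisnpError("n_reps must be >= 1")
    labs = list(labels) if labels is not None else list(sequences)
    codes = _codes_matrix(sequences, labs)
    n_cols = codes.shape[1]
    if n_cols < 2:
        raise VitisnpError("bootstrap needs an alignment with >= 2 columns")

    point = nj_tree(k2p_matrix_from_codes(codes, labs))
    point_bips = tree_bipartitions(point)
    counts = {b: 0 for b in point_bips}

    rng = np.random.default_rng(seed)
    n_eff = 0
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        try:
            rep_tree = nj_tree(k2p_matrix_from_codes(codes[:, cols], labs))
        except UndefinedDistanceError:
            continue
        n_eff += 1
        rep_bips = tree_bipartitions(rep_tree)
        for b in point_bips:
            if b in rep_bips:
                counts[b] += 1

    denom = n_eff if n_eff else 1
    supports = {b: 100.0 * c / denom for b, c in counts.items()}

    # annotate internal nodes of the point tree with integer percent labels
    leaves = sorted(labs)
    ref = leaves[0]
    all_set = frozenset(leaves)
    for node in point.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = _leafset(node)
        key = side if ref not in side else all_set - side
        if key in supports:
            node.label = str(int(round(supports[key])))
    return BootstrapResult(tree=point, supports=supports, n_replicates=n_reps, n_effective=n_eff)
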