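"""Neighbor-joining trees, bootstrap support, Newick I/O and tree comparison.

Neighbor joining is the standard agglomerative algorithm: at each step the
pair minimizing Q(i,j) = (r-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k) is
joined, branch lengths are b(i,u) = d(i,j)/2 + [sum_k d(i,k) - sum_k d(j,k)]
/ (2(r-2)), and the joined node enters the matrix with d(u,k) =
[d(i,k) + d(j,k) - d(i,j)] / 2.  Ties in Q are broken by the
lexicographically smallest label pair so runs are deterministic; negative
branch lengths are clamped to zero with the deficit moved to the sibling
edge (Kuhner-Felsenstein convention) and logged.  Trees are unrooted with a
degree-3 seed node.  NJ is consistent on additive matrices: it recovers the
generating topology exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .distances import DistanceMatrix, matrix_from_codes
from .seqstore import AlignedSet

logger = logging.getLogger(__name__)


class UndefinedDistanceError(ValueError):
    pass


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Build the neighbor-joining tree for a distance matrix (>= 3 taxa)."""
    if dm.undefined_pairs:
        raise UndefinedDistanceError(
            f"matrix has undefined entries: {dm.undefined_pairs[:5]}"
        )
    r = len(dm.labels)
    if r < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    tns = dendropy.TaxonNamespace(dm.labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(l)) for l in dm.labels]
    # tie-break key per cluster: smallest contained leaf label
    keys = list(dm.labels)
    D = dm.values.astype(float).copy()
    active = list(range(r))

    def join(i_pos: int, j_pos: int, bi: float, bj: float) -> None:
        nonlocal D, active, nodes, keys
        i, j = active[i_pos], active[j_pos]
        if bi < 0:
            logger.info("clamping negative branch length %.6g", bi)
            bj += bi
            bi = 0.0
        if bj < 0:
            logger.info("clamping negative branch length %.6g", bj)
            bi += bj
            bj = 0.0
            bi = max(bi, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = bi + 0.0  # + 0.0 normalizes IEEE -0.0
        nodes[j].edge.length = bj + 0.0
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        Qm = (m - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(Qm, np.inf)
        qmin = Qm.min()
        cand = np.argwhere(Qm <= qmin + 1e-12)
        best = min(
            (tuple(sorted((keys[active[a]], keys[active[b]]))), a, b)
            for a, b in cand
            if a < b
        )
        i_pos, j_pos = best[1], best[2]
        dij = sub[i_pos, j_pos]
        bi = dij / 2.0 + (rowsum[i_pos] - rowsum[j_pos]) / (2.0 * (m - 2))
        bj = dij - bi
        join(i_pos, j_pos, bi, bj)
        i, j = active[i_pos], active[j_pos]
        u = len(D)
        newrow = np.zeros(u + 1)
        for pos, k in enumerate(active):
            if k in (i, j):
                continue
            newrow[k] = (D[i, k] + D[j, k] - D[i, j]) / 2.0
        D = np.pad(D, ((0, 1), (0, 1)))
        D[u, : u + 1] = newrow
        D[: u + 1, u] = newrow
        active = [k for k in active if k not in (i, j)] + [u]

    # final degree-3 resolution: b(i) = (d(i,j) + d(i,k) - d(j,k)) / 2
    i, j, k = active
    center = dendropy.Node()
    for a, b, c in ((i, j, k), (j, i, k), (k, i, j)):
        length = (D[a, b] + D[a, c] - D[b, c]) / 2.0
        if length < 0:
            logger.info("clamping negative terminal branch length %.6g", length)
            length = 0.0
        center.add_child(nodes[a])
        nodes[a].edge.length = length + 0.0

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def _bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as leaf-label sets on the side away from the
    globally smallest label (an unrooted-tree normal form)."""
    all_labels = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(all_labels)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = all_labels - side
        if 1 < len(side) < len(all_labels) - 1:
            out.add(side)
    return out


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance: bipartitions present in exactly one tree."""
    b1, b2 = _bipartitions(t1), _bipartitions(t2)
    return len(b1 ^ b2)


@dataclass
class BootstrapResult:
    tree: dendropy.Tree  # point-estimate tree with supports as node labels
    supports: dict[frozenset[str], float]  # bipartition -> percent support
    n_failed: int  # replicates that never yielded defined distances


def bootstrap_support(
    aligned: AlignedSet,
    model: str = "K2P",
    n_reps: int = 500,
    seed: int | None = None,
    max_retries: int = 10,
) -> BootstrapResult:
    """Column-resampling bootstrap support on the NJ point-estimate tree.

    Each replicate resamples masked columns with replacement to the original
    masked length, recomputes distances and NJ, and the support of each
    internal edge of the point tree is the percentage of replicates whose
    tree contains the same bipartition.  Replicates with undefined distances
    are redrawn up to ``max_retries`` times, then counted as non-supporting.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    codes = aligned.masked_matrix()
    n_cols = codes.shape[1]
    point_dm = matrix_from_codes(codes, aligned.labels, model)
    point = nj_tree(point_dm)
    target = _bipartitions(point)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    n_failed = 0
    for _ in range(n_reps):
        for _attempt in range(max_retries):
            idx = rng.integers(0, n_cols, size=n_cols)
            dm = matrix_from_codes(codes[:, idx], aligned.labels, model)
            if not dm.undefined_pairs:
                break
        else:
            n_failed += 1
            logger.warning("bootstrap replicate failed after %d redraws", max_retries)
            continue
        reps = _bipartitions(nj_tree(dm))
        for bp in target:
            if bp in reps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    annotate_supports(point, supports)
    return BootstrapResult(point, supports, n_failed)


def annotate_supports(tree: dendropy.Tree, supports: dict[frozenset[str], float]) -> None:
    all_labels = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(all_labels)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = all_labels - side
        if side in supports:
            node.label = f"{supports[side]:.0f}"


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
    )


def read_newick(text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
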