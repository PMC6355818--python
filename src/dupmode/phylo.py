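"""Neighbor-joining tree construction, rooting and clade extraction.

NJ follows Saitou-Nei: at each step join the pair minimising
Q(i,j) = (n-2) d(i,j) - R_i - R_j, with the standard two-point branch
lengths. Ties are broken lexicographically by the smallest leaf label in
each cluster, so the result is fully deterministic. Trees are dendropy
objects throughout; midpoint rooting, Newick I/O and topology comparison
delegate to dendropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

log = logging.getLogger(__name__)

PhyloTree = dendropy.Tree


class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise PhyloError("duplicate labels in distance matrix")
        if self.d.shape != (n, n):
            raise PhyloError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise PhyloError("asymmetric distance matrix")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise PhyloError("non-zero diagonal in distance matrix")
        if np.any(self.d < -1e-12):
            raise PhyloError("negative distances")


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor joining; the result is the unrooted NJ tree stored with a
    trifurcation at the last join. Negative branch lengths are clamped to
    zero (raw value logged)."""
    n = len(dm.labels)
    if n < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=tns)

    nodes: list[dendropy.Node] = []
    minlab: list[str] = []
    for lab in dm.labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(lab)
        nodes.append(node)
        minlab.append(lab)
    d = dm.d.copy()

    def clamp(val: float) -> float:
        if val < 0:
            log.debug("clamping negative NJ branch length %g to 0", val)
            return 0.0
        return val

    while len(nodes) > 2:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        q = np.minimum(q, q.T)  # exact symmetry despite float summation order
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] == qmin:
                    key = tuple(sorted((minlab[i], minlab[j])))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        ci, cj = nodes[i], nodes[j]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = clamp(li)
        cj.edge.length = clamp(lj)
        dnew = 0.5 * (d[:, i] + d[:, j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[:-1, -1] = d2[-1, :-1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        minlab = [minlab[k] for k in keep] + [min(minlab[i], minlab[j])]

    u, v = nodes
    dist = d[0, 1]
    if u.is_leaf() and not v.is_leaf():
        u, v = v, u
    # attach the remainder to the internal node: classic trifurcating storage
    u.add_child(v)
    v.edge.length = clamp(dist)
    tree.seed_node = u
    return tree


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root a copy of the tree at the midpoint of its longest leaf-to-leaf
    path; leaf-to-leaf path lengths are preserved."""
    rooted = tree.clone(depth=1)
    for edge in rooted.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    if sum(e.length for e in rooted.preorder_edge_iter()
           if e.length is not None) == 0.0:
        log.warning("all branch lengths are zero; rooting on the first edge")
        leaf = next(rooted.leaf_node_iter())
        rooted.reroot_at_edge(leaf.edge, update_bipartitions=False)
        return rooted
    rooted.reroot_at_midpoint(update_bipartitions=False)
    return rooted


def clade_with_anchors(tree: PhyloTree, anchors: set[str]) -> set[str]:
    """Leaf labels of the smallest clade (MRCA subtree) holding all anchors.

    This is how the analysed subfamily ("group I": the query enzyme plus its
    in-genome homologs) is delimited from the full tree.
    """
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    for a in anchors:
        if a not in leaf_labels:
            raise PhyloError(f"anchor {a!r} is not a leaf of the tree")
    tree.is_rooted = True  # precondition: the seed node is the root
    taxa = [tree.taxon_namespace.get_taxon(a) for a in anchors]
    mrca = tree.mrca(taxa=taxa)
    return {lf.taxon.label for lf in mrca.leaf_iter()}


def leaf_distances(tree: PhyloTree) -> dict[tuple[str, str], float]:
    """Patristic (path-length) distances between all leaf pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            key = tuple(sorted((t1.label, t2.label)))
            out[key] = pdm.patristic_distance(t1, t2)
    return out


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True,
                                unquoted_underscores=True))


def read_newick(path) -> PhyloTree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
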