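"""Independent brute-force oracles used by the test suite.

Each oracle enumerates or searches exhaustively at tiny problem sizes and
deliberately shares no code path with the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


# ------------------------------------------------ alignment enumeration

def _subst(x: str, y: str, protein: bool, match: float, mismatch: float) -> float:
    if protein:
        return float(_BLOSUM62[x, y])
    return match if x == y else mismatch


def brute_global_score(a: str, b: str, protein: bool = True,
                       match: float = 1.0, mismatch: float = -2.0,
                       gap_open: float = -11.0, gap_extend: float = -1.0,
                       ) -> float:
    """Exhaustive recursion over every global alignment (no memoisation).

    A gap of length L costs gap_open + L*gap_extend; a deletion directly
    following an insertion (or vice versa) opens a new gap.
    """

    def rec(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            best = max(best, _subst(a[i], b[j], protein, match, mismatch)
                       + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend + (gap_open if last != "D" else 0.0)
            best = max(best, cost + rec(i + 1, j, "D"))
        if j < len(b):
            cost = gap_extend + (gap_open if last != "I" else 0.0)
            best = max(best, cost + rec(i, j + 1, "I"))
        return best

    return rec(0, 0, "M")


def brute_local_score(a: str, b: str, **kw) -> float:
    """Optimal local score: max global score over all substring pairs,
    floored at the empty alignment (score 0)."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(best, brute_global_score(a[i1:i2], b[j1:j2], **kw))
    return best


# ------------------------------------------- exhaustive least-squares NJ

def all_unrooted_topologies(labels: list[str]) -> list[dict]:
    """Every unrooted binary topology on the labels, as adjacency dicts.

    Grown by inserting each successive leaf into every edge; nodes are leaf
    labels (str) or internal ints.
    """
    assert len(labels) >= 3
    base = {"__i0": set(labels[:3])}
    for lab in labels[:3]:
        base[lab] = {"__i0"}
    trees = [base]
    for k, lab in enumerate(labels[3:], start=1):
        new_trees = []
        for t in trees:
            edges = {tuple(sorted((u, v))) for u in t for v in t[u]}
            for u, v in edges:
                t2 = {n: set(nb) for n, nb in t.items()}
                mid = f"__i{k}_{u}_{v}"
                t2[u].discard(v)
                t2[v].discard(u)
                t2[u].add(mid)
                t2[v].add(mid)
                t2[mid] = {u, v, lab}
                t2[lab] = {mid}
                new_trees.append(t2)
        trees = new_trees
    return trees


def _leaf_paths(tree: dict, labels: list[str]) -> dict[tuple[str, str], list]:
    """Edge list of the unique path between each leaf pair."""
    paths = {}
    for a, b in itertools.combinations(labels, 2):
        # BFS from a to b
        prev = {a: None}
        queue = [a]
        while queue:
            node = queue.pop(0)
            if node == b:
                break
            for nb in tree[node]:
                if nb not in prev:
                    prev[nb] = node
                    queue.append(nb)
        path = []
        node = b
        while prev[node] is not None:
            path.append(tuple(sorted((node, prev[node]))))
            node = prev[node]
        paths[(a, b)] = path
    return paths


def ls_fit_rss(tree: dict, labels: list[str], dmat: np.ndarray) -> float:
    """Residual sum of squares of the unconstrained least-squares branch
    fit of the topology to the distance matrix."""
    edges = sorted({tuple(sorted((u, v))) for u in tree for v in tree[u]})
    eidx = {e: i for i, e in enumerate(edges)}
    paths = _leaf_paths(tree, labels)
    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        for e in paths[(labels[i], labels[j])]:
            A[r, eidx[e]] = 1.0
        y[r] = dmat[i, j]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum((A @ x - y) ** 2))


def best_ls_topology(labels: list[str], dmat: np.ndarray) -> frozenset:
    """Splits of the minimum-RSS topology over the exhaustive search."""
    best = None
    for t in all_unrooted_topologies(labels):
        rss = ls_fit_rss(t, labels, dmat)
        if best is None or rss < best[0] - 1e-12:
            best = (rss, t)
    return topology_splits(best[1], labels)


def topology_splits(tree: dict, labels: list[str]) -> frozenset:
    """Non-trivial bipartitions of an adjacency-dict unrooted tree."""
    labset = set(labels)
    splits = set()
    for u in tree:
        for v in tree[u]:
            # leaves on v's side of edge (u, v)
            seen = {u, v}
            stack = [v]
            side = set()
            while stack:
                node = stack.pop()
                if node in labset:
                    side.add(node)
                for nb in tree[node]:
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            if 1 < len(side) < len(labset) - 1:
                splits.add(frozenset([frozenset(side),
                                      frozenset(labset - side)]))
    return frozenset(splits)


def dendropy_splits(tree, labels: list[str]) -> frozenset:
    """Same bipartition representation for a dendropy tree (unrooted view)."""
    labset = set(labels)
    splits = set()
    for node in tree.preorder_node_iter():
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if 1 < len(side) < len(labset) - 1:
            splits.add(frozenset([frozenset(side),
                                  frozenset(labset - side)]))
    return frozenset(splits)


# --------------------------------------------------- Dollo brute force

def brute_dollo_min_losses(tree, leaf_states: dict[str, int],
                           force_root_one: bool = True) -> int:
    """Minimum 1->0 transitions over all irreversible-loss assignments.

    Internal node states are enumerated exhaustively; a phantom always-1
    stem above the root is included when the root state is forced, so an
    all-intronless tree costs exactly one loss.
    """
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = [n for n in tree.leaf_node_iter()]
    best = None
    for assignment in itertools.product((0, 1), repeat=len(internals)):
        state = {n: s for n, s in zip(internals, assignment)}
        for lf in leaves:
            state[lf] = leaf_states[lf.taxon.label]
        valid = True
        losses = 0
        for node in internals:
            for child in node.child_nodes():
                if state[node] == 0 and state[child] == 1:
                    valid = False
                    break
                if state[node] == 1 and state[child] == 0:
                    losses += 1
            if not valid:
                break
        if not valid:
            continue
        if force_root_one and state[tree.seed_node] == 0:
            losses += 1  # loss on the phantom stem above the root
        if best is None or losses < best:
            best = losses
    return best


# ------------------------------------------------ naive promoter matcher

def naive_promoter_counts(seq: str, elements, both_strands: bool = True):
    """Position-by-position matcher with (element, position) dedup,
    mirroring the scanner's palindrome rule."""
    from dupmode.genome_io import reverse_complement
    seq = seq.upper()
    seen = set()
    counts = {el.name: 0 for el in elements}
    for el in elements:
        probes = []
        for pat in el.expanded():
            probes.append(pat)
        for i in range(len(seq)):
            matched = False
            for pat in probes:
                if seq.startswith(pat, i):
                    matched = True
                    break
                if both_strands and seq.startswith(reverse_complement(pat), i):
                    matched = True
                    break
            if matched and (el.name, i + 1) not in seen:
                seen.add((el.name, i + 1))
                counts[el.name] += 1
    return counts


# ---------------------------------------------------- random test trees

def random_binary_tree(labels: list[str], rng: np.random.Generator,
                       min_bl: float = 0.05, max_bl: float = 1.0):
    """Random rooted binary dendropy tree with uniform branch lengths."""
    import dendropy
    tns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        n = dendropy.Node()
        n.taxon = tns.get_taxon(lab)
        n.edge.length = float(rng.uniform(min_bl, max_bl))
        nodes.append(n)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(min_bl, max_bl))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[0]
    return tree


def tree_distance_matrix(tree, labels: list[str]) -> np.ndarray:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]],
                                                       taxa[labels[j]])
    return d
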