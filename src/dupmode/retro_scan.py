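"""Retroduplication inference.

Three independent lines of evidence are combined:

1. **Dollo intron-state reconstruction.** Intron presence is a binary
   character (1 = has at least one intron, 0 = intronless) assumed gained
   once in the family ancestor and lost irreversibly. Ancestral states are
   the OR of the leaf states below each node, which provably minimises the
   number of 1->0 transitions subject to the no-regain constraint; every
   edge whose parent is 1 and child is 0 marks a candidate retroduplication.
2. **Poly(A) tails.** A retrocopy derives from a polyadenylated mRNA, so its
   3' flank may begin with an A-rich stretch. The scanner reports the
   earliest A-rich window or A-run within a configurable search depth.
3. **Target-site duplications.** Genomic reinsertion by staggered-cut repair
   leaves short direct repeats flanking the insert; the scanner compares the
   terminal window of the 5' flank with the initial window of the 3' flank.

Because a retrocopy may later be tandem- or segmentally duplicated (the
copies inherit intronlessness without being retrogenes themselves), the
per-gene retro call is *pinpointed*: within each Dollo loss clade, members
carrying flank evidence take the call; a clade with no surviving flank
evidence keeps the whole-clade flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy

from .phylo import PhyloTree

log = logging.getLogger(__name__)


class RetroScanError(ValueError):
    pass


# --------------------------------------------------- Dollo reconstruction

@dataclass
class RetroInference:
    """Ancestral intron states and the loss edges they imply.

    ``node_states`` maps dendropy nodes to {0,1}; ``loss_edges`` holds
    (parent, child) node pairs with parent=1, child=0. When every leaf is
    intronless and the root state is forced to 1, the single loss sits on a
    phantom stem above the root, represented as (None, root).
    """

    node_states: dict
    loss_edges: list[tuple]
    root_forced: bool

    @property
    def n_losses(self) -> int:
        return len(self.loss_edges)


def dollo_reconstruct(tree: PhyloTree, states: dict[str, int],
                      force_root_state_one: bool = True) -> RetroInference:
    """Minimum-loss Dollo assignment of intron presence on a rooted tree.

    Each node's state is the OR of its leaves' states: losses are then
    exactly the stems of the maximal intronless subtrees, which is the
    unique minimum under irreversible loss. With ``force_root_state_one``
    (the default: the family ancestor carried introns) an all-intronless
    tree still implies one loss, placed on the root's stem.
    """
    node_states: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            if label not in states:
                raise RetroScanError(f"leaf {label!r} has no intron state")
            s = int(states[label])
            if s not in (0, 1):
                raise RetroScanError(f"leaf {label!r}: state must be 0 or 1")
            node_states[node] = s
        else:
            node_states[node] = int(any(node_states[c]
                                        for c in node.child_nodes()))
    loss_edges = []
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            if node_states[node] == 1 and node_states[child] == 0:
                loss_edges.append((node, child))
    root = tree.seed_node
    if force_root_state_one and node_states[root] == 0:
        loss_edges = [(None, root)]
    return RetroInference(node_states=node_states, loss_edges=loss_edges,
                          root_forced=force_root_state_one)


def infer_retro_events(inference: RetroInference,
                       tree: PhyloTree) -> list[tuple[tuple, set[str]]]:
    """One candidate retroduplication per loss edge, with the leaf set it
    subtends; callers annotate those leaves retro_signature=True."""
    events = []
    for parent, child in inference.loss_edges:
        leaves = {lf.taxon.label for lf in child.leaf_iter()}
        events.append(((parent, child), leaves))
    return events


def annotate_loss_edges(tree: PhyloTree, inference: RetroInference,
                        mark: str = "R") -> str:
    """Newick string with loss-edge children labelled (internal nodes get
    the mark as label, leaves get it appended) for figure-style export."""
    annotated = tree.clone(depth=1)
    # clone preserves structure; map loss children by their leaf sets
    loss_leafsets = [frozenset(lf.taxon.label for lf in child.leaf_iter())
                     for _, child in inference.loss_edges]
    for node in annotated.preorder_node_iter():
        leafset = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if leafset in loss_leafsets:
            if node.is_leaf():
                node.taxon.label = f"{node.taxon.label}[{mark}]"
            else:
                node.label = mark
    return annotated.as_string(schema="newick", suppress_rooting=True,
                               unquoted_underscores=True)


# ------------------------------------------------------- poly(A) scanning

@dataclass
class PolyAHit:
    gene_id: str
    offset_bp: int        # 0-based offset into the 3' flank
    window_len: int
    A_fraction: float


def detect_polyA(flank3: str, search_depth_bp: int = 300,
                 window_len: int = 15, min_A_fraction: float = 0.8,
                 min_run: int = 8, gene_id: str = "") -> PolyAHit | None:
    """Earliest poly(A)-like signal in a gene-strand-oriented 3' flank.

    A position qualifies through either criterion: a ``window_len`` window
    with A fraction >= ``min_A_fraction``, or a run of >= ``min_run``
    consecutive A's starting there. The earlier qualifying offset wins.
    Returns None when nothing qualifies (an empty flank logs a warning).
    """
    if not flank3:
        log.warning("empty 3' flank for %s; poly(A) scan skipped", gene_id)
        return None
    seq = flank3.upper()
    depth = min(search_depth_bp, len(seq))
    for off in range(depth):
        run = 0
        for ch in seq[off:]:
            if ch != "A":
                break
            run += 1
        if run >= min_run:
            # report the whole uninterrupted run
            return PolyAHit(gene_id, off, run, 1.0)
        window = seq[off:off + window_len]
        if len(window) == window_len:
            frac = window.count("A") / window_len
            if frac >= min_A_fraction:
                return PolyAHit(gene_id, off, window_len, frac)
    return None


# ------------------------------------------- direct repeat (TSD) scanning

@dataclass
class DirectRepeatHit:
    gene_id: str
    repeat_seq: str
    pos5: int             # 1-based start within the full 5' flank
    pos3: int             # 1-based start within the full 3' flank
    length: int
    mismatches: int


def detect_direct_repeats(flank5: str, flank3: str,
                          window5_bp: int = 100, window3_bp: int = 100,
                          min_len: int = 8, max_mismatch: int = 1,
                          gene_id: str = "") -> list[DirectRepeatHit]:
    """All maximal shared substrings between the end of the 5' flank and the
    start of the 3' flank, allowing up to ``max_mismatch`` substitutions.

    A true target-site duplication sits immediately upstream of the insert
    and immediately after its poly(A), hence the two windows. Hits are
    sorted by descending length, then by position; an empty result is the
    expected outcome for non-retro genes (and, per the source analysis of
    eroded retrocopies, often for true ones too).
    """
    w5 = flank5[-window5_bp:] if flank5 else ""
    w3 = flank3[:window3_bp] if flank3 else ""
    off5 = len(flank5) - len(w5)
    if min(len(w5), len(w3)) < min_len:
        return []
    hits: list[DirectRepeatHit] = []
    n5, n3 = len(w5), len(w3)
    # walk each diagonal; maximal <=k-mismatch windows lie between the
    # mismatch positions that bound them
    for diag in range(-(n5 - 1), n3):
        i0 = max(0, -diag)
        j0 = i0 + diag
        length = min(n5 - i0, n3 - j0)
        if length < min_len:
            continue
        mism = [p for p in range(length) if w5[i0 + p] != w3[j0 + p]]
        bounds = [-1] + mism + [length]
        t = len(mism)
        k = max_mismatch
        if t <= k:
            windows = [(0, length - 1, t)]
        else:
            windows = []
            for a in range(t - k + 1):
                lo = bounds[a] + 1            # just after previous mismatch
                hi = bounds[a + k + 1] - 1    # just before the (k+1)-th
                inside = sum(1 for p in mism if lo <= p <= hi)
                windows.append((lo, hi, inside))
        for lo, hi, inside in windows:
            wlen = hi - lo + 1
            if wlen >= min_len:
                hits.append(DirectRepeatHit(
                    gene_id=gene_id,
                    repeat_seq=w3[j0 + lo:j0 + hi + 1],
                    pos5=off5 + i0 + lo + 1,
                    pos3=j0 + lo + 1,
                    length=wlen,
                    mismatches=inside,
                ))
    hits.sort(key=lambda h: (-h.length, h.mismatches, h.pos5, h.pos3))
    return hits


# ---------------------------------------------------------- pinpointing

def pinpoint_retro(events: list[tuple[tuple, set[str]]],
                   flank_evidence: dict[str, bool]) -> set[str]:
    """Resolve per-gene retro calls from Dollo loss clades + flank evidence.

    Within each loss clade, genes with flank evidence (poly(A) and direct
    repeat) take the retro call; a clade with no evidenced member keeps the
    flag on every member (intronlessness alone then carries the call).
    Evidenced genes outside any loss clade are also flagged: a retrocopy of
    an already-intronless gene leaves no intron-loss footprint.
    """
    flagged: set[str] = set()
    clade_members: set[str] = set()
    for _edge, leaves in events:
        clade_members |= leaves
        evidenced = {g for g in leaves if flank_evidence.get(g)}
        flagged |= evidenced if evidenced else leaves
    flagged |= {g for g, ok in flank_evidence.items()
                if ok and g not in clade_members}
    return flagged
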