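"""Tandem-array and segmental-pair detection, and duplication-mode calls.

Tandem arrays are physical chains of family genes (bounded base-pair gap,
bounded number of intervening non-family genes) corroborated by tree
sisterhood; segmental duplicates are all-vs-all CDS pairs passing the
similarity filter (identity > 80%, E < 1e-10 by default) that do not sit
inside one tandem array. Every family gene then receives one
DuplicationCall with precedence retro > tandem > segmental > unclassified.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

from .align_search import DNA_PARAMS, AlignParams, pairwise_align
from .genome_io import GeneModel, GeneSequences
from .phylo import PhyloTree

log = logging.getLogger(__name__)


class DupEventsError(ValueError):
    pass


# --------------------------------------------------------- tandem arrays

@dataclass
class TandemCluster:
    cluster_id: str
    chrom: str
    members: tuple[str, ...]               # ordered by coordinate
    sisterhood_fraction: float
    member_sister_in_cluster: dict[str, bool] = field(default_factory=dict)

    @property
    def tandem_origin(self) -> bool:
        """An array is called tandem-born when at least half its members
        have their tree sister inside the array."""
        return self.sisterhood_fraction >= 0.5


def _sibling_leaves(tree: PhyloTree) -> dict[str, set[str]]:
    """For each leaf, the leaf labels of its sibling subtree(s) in the
    rooted tree (the clade(s) sharing its parent node)."""
    out: dict[str, set[str]] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        parent = leaf.parent_node
        sibs: set[str] = set()
        if parent is not None:
            for child in parent.child_nodes():
                if child is not leaf:
                    sibs |= {lf.taxon.label for lf in child.leaf_iter()}
        out[label] = sibs
    return out


def detect_tandem_clusters(models: list[GeneModel], tree: PhyloTree,
                           max_intervening_genes: int = 5,
                           max_gap_bp: int = 250_000,
                           all_models: list[GeneModel] | None = None,
                           ) -> list[TandemCluster]:
    """Chain family genes into physical arrays and score tree sisterhood.

    ``models`` are the family genes (must all be leaves of ``tree``);
    ``all_models`` is the complete annotation used to count intervening
    non-family genes (without it that criterion is vacuous). Chains of >= 2
    are kept; order of the input list does not matter.
    """
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    for m in models:
        if m.gene_id not in leaf_labels:
            raise DupEventsError(f"gene {m.gene_id} missing from tree")
    family_ids = {m.gene_id for m in models}
    others_by_chrom: dict[str, list[GeneModel]] = {}
    if all_models:
        for m in all_models:
            if m.gene_id not in family_ids:
                others_by_chrom.setdefault(m.chrom, []).append(m)
    sibs = _sibling_leaves(tree)

    clusters: list[TandemCluster] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in sorted(models, key=lambda m: (m.chrom, m.start, m.gene_id)):
        by_chrom.setdefault(m.chrom, []).append(m)
    idx = 0
    for chrom in sorted(by_chrom):
        chain: list[GeneModel] = []
        others = sorted(others_by_chrom.get(chrom, []), key=lambda m: m.start)

        def n_between(a: GeneModel, b: GeneModel) -> int:
            return sum(1 for o in others if o.start > a.end and o.end < b.start)

        def flush(chain: list[GeneModel]) -> None:
            nonlocal idx
            if len(chain) < 2:
                return
            member_ids = tuple(m.gene_id for m in chain)
            in_cluster = set(member_ids)
            sister_ok = {g: bool(sibs[g] & (in_cluster - {g}))
                        for g in member_ids}
            frac = sum(sister_ok.values()) / len(member_ids)
            idx += 1
            clusters.append(TandemCluster(
                cluster_id=f"TC{idx:02d}", chrom=chrom, members=member_ids,
                sisterhood_fraction=frac,
                member_sister_in_cluster=sister_ok))

        for m in by_chrom[chrom]:
            if chain and (m.start - chain[-1].end <= max_gap_bp
                          and n_between(chain[-1], m) <= max_intervening_genes):
                chain.append(m)
            else:
                flush(chain)
                chain = [m]
        flush(chain)
    return clusters


# ------------------------------------------------------- segmental pairs

@dataclass(frozen=True)
class SegmentalPair:
    gene_a: str
    gene_b: str
    identity_pct: float
    evalue: float
    reciprocal_best: bool = False


def detect_segmental_pairs(gene_seqs: list[GeneSequences],
                           params: AlignParams = DNA_PARAMS,
                           identity_threshold: float = 80.0,
                           evalue_threshold: float = 1e-10,
                           clusters: list[TandemCluster] | None = None,
                           ) -> list[SegmentalPair]:
    """All-vs-all CDS comparison at the similarity thresholds.

    Pairs pass when identity > ``identity_threshold`` (strict, the
    ">80%" rule) and E < ``evalue_threshold``; pairs whose two genes sit in
    the same tandem array are excluded so the two mechanisms stay disjoint.
    ``reciprocal_best`` marks pairs where each gene is the other's
    highest-identity partner over all comparisons.
    """
    if len(gene_seqs) < 2:
        raise DupEventsError("need at least 2 genes for segmental detection")
    cluster_of: dict[str, str] = {}
    for cl in clusters or []:
        for g in cl.members:
            cluster_of[g] = cl.cluster_id
    best: dict[str, tuple[float, str]] = {}
    raw: list[SegmentalPair] = []
    for ga, gb in itertools.combinations(gene_seqs, 2):
        if not ga.cds or not gb.cds:
            continue
        r = pairwise_align(ga.cds, gb.cds, params, compute_evalue=True)
        ident = r.identity_pct
        for x, y in ((ga.gene_id, gb.gene_id), (gb.gene_id, ga.gene_id)):
            if x not in best or ident > best[x][0]:
                best[x] = (ident, y)
        same_cluster = (ga.gene_id in cluster_of and
                        cluster_of.get(ga.gene_id) == cluster_of.get(gb.gene_id))
        if ident > identity_threshold and r.evalue < evalue_threshold \
                and not same_cluster:
            a, b = sorted((ga.gene_id, gb.gene_id))
            raw.append(SegmentalPair(a, b, ident, r.evalue))
    return [
        SegmentalPair(p.gene_a, p.gene_b, p.identity_pct, p.evalue,
                      reciprocal_best=(best.get(p.gene_a, (0, ""))[1] == p.gene_b
                                       and best.get(p.gene_b, (0, ""))[1] == p.gene_a))
        for p in raw
    ]


# ------------------------------------------------------------ mode calls

MODES = ("tandem", "segmental", "retro", "unclassified")


@dataclass
class DuplicationCall:
    gene_id: str
    chrom: str
    start: int
    end: int
    in_tandem_cluster: bool = False
    cluster_id: str = ""
    segmental_partners: tuple[str, ...] = ()
    retro_signature: bool = False
    primary_mode: str = "unclassified"


def assign_modes(models: list[GeneModel],
                 clusters: list[TandemCluster],
                 pairs: list[SegmentalPair],
                 retro_primary: set[str],
                 retro_dollo: set[str] | None = None,
                 max_call_gap_bp: int = 25_000,
                 ) -> list[DuplicationCall]:
    """One DuplicationCall per family gene; precedence retro > tandem >
    segmental > unclassified.

    ``retro_primary`` holds the pinpointed retrogene calls (Dollo loss
    clades refined by flank evidence); ``retro_dollo`` optionally widens the
    retro_signature *flag* to every leaf under a loss edge. Tandem calls go
    to array members other than the array founder -- the most upstream
    member, because unequal crossing-over inserts copies downstream of
    their donor -- and other than retro-called members (a retrogene may
    found or join an array without being a tandem copy). Leaf sisterhood is
    reported per cluster as a diagnostic but does not gate the calls: a
    member's tree sister stops being its array neighbour as soon as either
    of them donates a later copy elsewhere.

    Chaining (cluster detection) and calling operate at two physical
    scales: arrays are chained loosely (``max_gap_bp``, tolerant of decayed
    or interleaved arrays), but a *tandem call* additionally requires the
    gene to lie within ``max_call_gap_bp`` of another member -- unequal
    crossing-over creates immediately adjacent copies, whereas an unrelated
    family gene that merely landed inside the chaining window is typically
    tens of kilobases from its nearest neighbour.
    """
    ids = [m.gene_id for m in models]
    if len(set(ids)) != len(ids):
        raise DupEventsError("duplicate gene ids in mode assignment")
    partners: dict[str, set[str]] = {g: set() for g in ids}
    for p in pairs:
        if p.gene_a in partners:
            partners[p.gene_a].add(p.gene_b)
        if p.gene_b in partners:
            partners[p.gene_b].add(p.gene_a)
    cluster_of: dict[str, TandemCluster] = {}
    for cl in clusters:
        for g in cl.members:
            cluster_of[g] = cl
    start_of = {m.gene_id: m.start for m in models}
    founders: set[str] = set()
    for cl in clusters:
        founders.add(min(cl.members, key=lambda g: start_of.get(g, 0)))
    retro_flags = set(retro_primary) | set(retro_dollo or ())

    end_of = {m.gene_id: m.end for m in models}

    def near_member(g: str, cl: TandemCluster) -> bool:
        gaps = []
        ordered = sorted(cl.members, key=lambda x: start_of.get(x, 0))
        i = ordered.index(g)
        if i > 0:
            gaps.append(start_of[g] - end_of[ordered[i - 1]])
        if i < len(ordered) - 1:
            gaps.append(start_of[ordered[i + 1]] - end_of[g])
        return bool(gaps) and min(gaps) <= max_call_gap_bp

    calls = []
    for m in models:
        cl = cluster_of.get(m.gene_id)
        in_tandem = cl is not None
        tandem_call = (in_tandem and m.gene_id not in founders
                       and near_member(m.gene_id, cl))
        if m.gene_id in retro_primary:
            mode = "retro"
        elif tandem_call:
            mode = "tandem"
        elif partners[m.gene_id]:
            mode = "segmental"
        else:
            mode = "unclassified"
        calls.append(DuplicationCall(
            gene_id=m.gene_id, chrom=m.chrom, start=m.start, end=m.end,
            in_tandem_cluster=in_tandem,
            cluster_id=cl.cluster_id if cl else "",
            segmental_partners=tuple(sorted(partners[m.gene_id])),
            retro_signature=m.gene_id in retro_flags,
            primary_mode=mode))
    return calls


# ------------------------------------------------------------- reporting

def write_calls_tsv(calls: list[DuplicationCall], path) -> None:
    cols = ["gene_id", "chrom", "start", "end", "primary_mode",
            "in_tandem_cluster", "cluster_id", "segmental_partners",
            "retro_signature"]
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in sorted(calls, key=lambda c: (c.chrom, c.start, c.gene_id)):
            fh.write("\t".join([
                c.gene_id, c.chrom, str(c.start), str(c.end), c.primary_mode,
                str(int(c.in_tandem_cluster)), c.cluster_id or ".",
                ",".join(c.segmental_partners) or ".",
                str(int(c.retro_signature)),
            ]) + "\n")


def write_calls_json(calls: list[DuplicationCall], path) -> None:
    payload = [c.__dict__ | {"segmental_partners": list(c.segmental_partners)}
               for c in sorted(calls, key=lambda c: c.gene_id)]
    with open(path, "w", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_clusters_bed(clusters: list[TandemCluster],
                       models: list[GeneModel], path) -> None:
    """Cluster spans as BED (0-based half-open: start-1, end)."""
    span = {m.gene_id: (m.start, m.end) for m in models}
    with open(path, "w", newline="\n") as fh:
        for cl in sorted(clusters, key=lambda c: c.cluster_id):
            starts = [span[g][0] for g in cl.members if g in span]
            ends = [span[g][1] for g in cl.members if g in span]
            if starts:
                fh.write(f"{cl.chrom}\t{min(starts) - 1}\t{max(ends)}\t"
                         f"{cl.cluster_id}\t{len(cl.members)}\t.\n")
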