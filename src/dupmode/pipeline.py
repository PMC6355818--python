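"""End-to-end orchestration: simulate/load -> identify -> tree -> classify
-> retro-scan -> promoter-scan -> report.

The pipeline is deterministic: given the same config (including seed) it
produces byte-identical artifacts, and the report embeds the config hash
so a run can be reproduced exactly from the report alone. Results go to
stdout-free files under ``outdir``; logging goes to standard error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .align_search import (PROTEIN_PARAMS, find_family,
                           poisson_distance_matrix, write_hit_table)
from .dup_events import (DuplicationCall, assign_modes, detect_segmental_pairs,
                         detect_tandem_clusters, write_calls_tsv,
                         write_clusters_bed)
from .genome_io import (GeneModel, SeqRecord, extract_gene_sequences,
                        parse_fasta, parse_gff3, write_fasta, write_gff3)
from .phylo import (DistanceMatrix, clade_with_anchors, midpoint_root, nj_tree,
                    write_newick)
from .promoter_scan import load_element_table, scan_promoter
from .retro_scan import (annotate_loss_edges, detect_direct_repeats,
                         detect_polyA, dollo_reconstruct, infer_retro_events,
                         pinpoint_retro)
from .synth_evolve import (EventRecord, SimConfig, read_truth, simulate,
                           write_truth)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of one analysis run.

    Exactly one of (``simulate``) and (``genome_path`` + ``gff_path`` +
    ``query_protein_path``) must be given.
    """

    outdir: str
    seed: int = 0
    simulate: SimConfig | None = None
    genome_path: str | None = None
    gff_path: str | None = None
    query_protein_path: str | None = None
    family_max_evalue: float = 1e-10
    tandem_max_gap_bp: int = 250_000
    tandem_max_intervening: int = 5
    tandem_call_max_gap_bp: int = 25_000
    segmental_identity: float = 80.0
    segmental_evalue: float = 1e-10
    polya_search_depth: int = 300
    polya_window: int = 15
    polya_min_fraction: float = 0.8
    polya_min_run: int = 8
    polya_evidence_max_offset: int = 50
    tsd_window: int = 100
    tsd_min_len: int = 8
    tsd_max_mismatch: int = 1
    promoter_bp: int = 2000
    promoter_both_strands: bool = True
    anchor_genes: tuple[str, ...] = ()
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        real = all(p is not None for p in
                   (self.genome_path, self.gff_path, self.query_protein_path))
        if (self.simulate is None) == (not real):
            raise ValueError("config needs exactly one of: a simulate block, "
                             "or genome+gff+query paths")

    # -- (de)serialisation --------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
            for key in ("ancestor_exon_lengths", "ancestor_intron_lengths",
                        "event_type_counts", "event_type_probs",
                        "promoter_elements_to_plant"):
                v = d["simulate"][key]
                if v is not None:
                    d["simulate"][key] = [list(x) if isinstance(x, tuple)
                                          else x for x in v]
        d["anchor_genes"] = list(self.anchor_genes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.get("simulate")
        if sim is not None:
            sim = dict(sim)
            for key in ("ancestor_exon_lengths", "ancestor_intron_lengths",
                        "event_type_counts"):
                if sim.get(key) is not None:
                    sim[key] = tuple(sim[key])
            if sim.get("event_type_probs") is not None:
                sim["event_type_probs"] = tuple(sim["event_type_probs"])
            if sim.get("promoter_elements_to_plant") is not None:
                sim["promoter_elements_to_plant"] = tuple(
                    (str(n), int(c)) for n, c in
                    sim["promoter_elements_to_plant"])
            sim.setdefault("seed", d.get("seed", 0))
            d["simulate"] = SimConfig(**sim)
        if d.get("anchor_genes") is not None:
            d["anchor_genes"] = tuple(d["anchor_genes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_sim_pipeline_config(outdir: str, seed: int = 42,
                                **sim_overrides) -> PipelineConfig:
    """The default simulated scenario: 12 events, 4 per mechanism."""
    return PipelineConfig(outdir=str(outdir), seed=seed,
                          simulate=SimConfig(seed=seed, **sim_overrides))


# ----------------------------------------------------------------- run

@dataclass
class AnalysisReport:
    data: dict

    def __getitem__(self, key):
        return self.data[key]

    def write(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(config: PipelineConfig, resume: bool = False) -> AnalysisReport:
    """Execute all stages in fixed order, persisting intermediates.

    With ``resume`` an existing report whose embedded config hash matches is
    returned untouched (idempotent reruns). Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report_path = out / "report.json"
    chash = config.config_hash()
    if resume and report_path.exists():
        data = json.loads(report_path.read_text())
        if data.get("provenance", {}).get("config_hash") == chash:
            log.info("report with matching config hash found; skipping run")
            return AnalysisReport(data)

    # -- stage: inputs -------------------------------------------------
    truth: list[EventRecord] = []
    if config.simulate is not None:
        log.info("stage inputs: simulating dataset (seed=%d)",
                 config.simulate.seed)
        ds = simulate(config.simulate)
        write_fasta(ds.genome, out / "genome.fasta")
        write_gff3(ds.models, out / "models.gff3")
        write_truth(ds, out / "truth.tsv")
        truth = ds.truth
        query_id = ds.query_id
        genome_path, gff_path = out / "genome.fasta", out / "models.gff3"
    else:
        for p in (config.genome_path, config.gff_path,
                  config.query_protein_path):
            if not Path(p).exists():
                raise PipelineError("inputs", f"missing input file: {p}")
        genome_path, gff_path = Path(config.genome_path), Path(config.gff_path)
        query_id = None

    genome = parse_fasta(genome_path)
    models = parse_gff3(gff_path)
    by_id = {m.gene_id: m for m in models}

    # -- stage: identify ----------------------------------------------
    log.info("stage identify: deriving proteins and harvesting the family")
    seqs = {}
    for m in models:
        try:
            seqs[m.gene_id] = extract_gene_sequences(genome, m)
        except Exception as exc:
            raise PipelineError("identify", f"{m.gene_id}: {exc}") from exc
    proteome = [SeqRecord(g, s.protein) for g, s in seqs.items() if s.protein]
    if config.simulate is not None:
        query = next(r for r in proteome if r.id == query_id)
    else:
        recs = parse_fasta(config.query_protein_path)
        query = recs[0]
        query_id = query.id
    hits = find_family(query, proteome, PROTEIN_PARAMS,
                       max_evalue=config.family_max_evalue)
    write_hit_table(hits, out / "family_hits.tsv")
    family_ids = sorted({rec.id for rec, _ in hits})
    hit_by_id = {rec.id: r for rec, r in hits}
    if len(family_ids) < 3:
        raise PipelineError("tree", f"family has {len(family_ids)} members; "
                            "need >= 3 for a tree")

    # -- stage: tree ---------------------------------------------------
    log.info("stage tree: %d family members", len(family_ids))
    fam_prot = [SeqRecord(g, seqs[g].protein) for g in family_ids]
    labels, dmat = poisson_distance_matrix(fam_prot)
    tree = nj_tree(DistanceMatrix(labels, dmat))
    rooted = midpoint_root(tree)
    write_newick(tree, out / "tree.nwk")
    write_newick(rooted, out / "rooted_tree.nwk")
    anchors = set(config.anchor_genes) or None
    group = sorted(clade_with_anchors(rooted, anchors)) if anchors \
        else list(family_ids)

    # -- stage: classify ----------------------------------------------
    log.info("stage classify: tandem arrays, segmental pairs, retro scan")
    fam_models = [by_id[g] for g in family_ids]
    clusters = detect_tandem_clusters(
        fam_models, rooted, max_intervening_genes=config.tandem_max_intervening,
        max_gap_bp=config.tandem_max_gap_bp, all_models=models)
    fam_seqs = [seqs[g] for g in family_ids]
    pairs = detect_segmental_pairs(
        fam_seqs, identity_threshold=config.segmental_identity,
        evalue_threshold=config.segmental_evalue, clusters=clusters)
    states = {g: (1 if by_id[g].intron_count > 0 else 0) for g in family_ids}
    inference = dollo_reconstruct(rooted, states)
    events = infer_retro_events(inference, rooted)
    polya, tsd = {}, {}
    for g in family_ids:
        polya[g] = detect_polyA(
            seqs[g].flank3, search_depth_bp=config.polya_search_depth,
            window_len=config.polya_window,
            min_A_fraction=config.polya_min_fraction,
            min_run=config.polya_min_run, gene_id=g)
        tsd_hits = detect_direct_repeats(
            seqs[g].flank5, seqs[g].flank3,
            window5_bp=config.tsd_window, window3_bp=config.tsd_window,
            min_len=config.tsd_min_len, max_mismatch=config.tsd_max_mismatch,
            gene_id=g)
        tsd[g] = tsd_hits[0] if tsd_hits else None
    # flank evidence for a retrogene: intronless, an A tract abutting the
    # gene end (a poly(A) tail sits at the cleavage site, not hundreds of
    # bases downstream), and a direct repeat
    evidence = {
        g: bool(states[g] == 0 and polya[g]
                and polya[g].offset_bp <= config.polya_evidence_max_offset
                and tsd[g])
        for g in family_ids}
    retro_primary = pinpoint_retro(events, evidence)
    retro_dollo = set().union(*(lv for _, lv in events)) if events else set()
    calls = assign_modes(fam_models, clusters, pairs, retro_primary,
                         retro_dollo=retro_dollo,
                         max_call_gap_bp=config.tandem_call_max_gap_bp)
    write_calls_tsv(calls, out / "calls.tsv")
    write_clusters_bed(clusters, fam_models, out / "clusters.bed")
    _write_retro_report(out / "retro_report.tsv", family_ids, by_id,
                        retro_primary, retro_dollo, polya, tsd)
    (out / "retro_tree.nwk").write_text(
        annotate_loss_edges(rooted, inference), newline="\n")

    # -- stage: promoter ----------------------------------------------
    log.info("stage promoter: scanning %d promoters", len(family_ids))
    elements = load_element_table()
    prom_counts = {}
    for g in family_ids:
        prom = extract_gene_sequences(genome, by_id[g],
                                      flank_bp=config.promoter_bp,
                                      translate_cds=False).flank5
        if prom:
            _, counts = scan_promoter(prom, elements,
                                      both_strands=config.promoter_both_strands)
        else:
            counts = {el.name: 0 for el in elements}
        prom_counts[g] = {k: v for k, v in counts.items() if v}
    _write_promoter_tsv(out / "promoter_counts.tsv", prom_counts)

    # -- stage: report -------------------------------------------------
    data = {
        "provenance": {"config_hash": chash, "seed": config.seed,
                       "package": "dupmode", "version": __version__},
        "query_id": query_id,
        "family": [
            {"gene_id": g, "chrom": by_id[g].chrom, "start": by_id[g].start,
             "end": by_id[g].end, "intron_count": by_id[g].intron_count,
             "identity_to_query": round(hit_by_id[g].identity_pct, 4),
             "evalue_vs_query": hit_by_id[g].evalue}
            for g in family_ids],
        "group": group,
        "tree_newick": (out / "tree.nwk").read_text(),
        "clusters": [
            {"cluster_id": c.cluster_id, "chrom": c.chrom,
             "members": list(c.members),
             "sisterhood_fraction": round(c.sisterhood_fraction, 6),
             "tandem_origin": c.tandem_origin}
            for c in clusters],
        "segmental_pairs": [
            {"gene_a": p.gene_a, "gene_b": p.gene_b,
             "identity_pct": round(p.identity_pct, 4), "evalue": p.evalue,
             "reciprocal_best": p.reciprocal_best}
            for p in pairs],
        "retro": {
            "n_loss_edges": inference.n_losses,
            "loss_clades": sorted(sorted(lv) for _, lv in events),
            "retro_genes": sorted(retro_primary),
            "polyA_hits": {g: {"offset": h.offset_bp, "len": h.window_len,
                               "A_fraction": round(h.A_fraction, 4)}
                           for g, h in polya.items() if h},
            "tsd_hits": {g: {"seq": h.repeat_seq, "len": h.length,
                             "mismatches": h.mismatches}
                         for g, h in tsd.items() if h},
        },
        "calls": {c.gene_id: c.primary_mode for c in calls},
        "promoter_counts": prom_counts,
    }
    report = AnalysisReport(data)
    report.write(report_path)
    log.info("report written to %s", report_path)
    return report


def _write_retro_report(path, family_ids, by_id, retro_primary, retro_dollo,
                        polya, tsd) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("gene_id\tintron_count\tretro_flag\tretro_call\t"
                 "polyA_offset\tpolyA_fraction\ttsd_len\ttsd_mismatches\n")
        for g in family_ids:
            ph, th = polya[g], tsd[g]
            fh.write("\t".join([
                g, str(by_id[g].intron_count),
                str(int(g in retro_dollo)), str(int(g in retro_primary)),
                str(ph.offset_bp) if ph else ".",
                f"{ph.A_fraction:.3f}" if ph else ".",
                str(th.length) if th else ".",
                str(th.mismatches) if th else ".",
            ]) + "\n")


def _write_promoter_tsv(path, prom_counts) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("gene_id\telement\tcount\n")
        for g in sorted(prom_counts):
            for el in sorted(prom_counts[g]):
                fh.write(f"{g}\t{el}\t{prom_counts[g][el]}\n")


# ----------------------------------------------------------- evaluation

def compare_to_truth(calls: list[DuplicationCall] | dict[str, str],
                     truth: list[EventRecord]) -> dict:
    """Score predicted modes against simulator truth, per event type.

    Only the *new* gene of each event is scored (the donor's own label
    belongs to the event that created *it*). Precision/recall are 1.0 by
    convention when a mode has no predictions / no true events. Raises on
    truth genes absent from the calls, listing the orphans.
    """
    mode_of = ({c.gene_id: c.primary_mode for c in calls}
               if not isinstance(calls, dict) else dict(calls))
    orphans = [r.new_gene_id for r in truth if r.new_gene_id not in mode_of]
    if orphans:
        raise ValueError("truth genes missing from calls: "
                         + ", ".join(sorted(orphans)))
    modes = ("tandem", "segmental", "retro", "unclassified")
    confusion = {t: {m: 0 for m in modes} for t in modes[:3]}
    for r in truth:
        confusion[r.type][mode_of[r.new_gene_id]] += 1
    per_mode = {}
    correct = 0
    for m in modes[:3]:
        n_true = sum(confusion[m].values())
        n_pred = sum(confusion[t][m] for t in confusion)
        tp = confusion[m][m]
        correct += tp
        per_mode[m] = {
            "n_true": n_true, "n_predicted": n_pred,
            "precision": tp / n_pred if n_pred else 1.0,
            "recall": tp / n_true if n_true else 1.0,
        }
    return {
        "n_events": len(truth),
        "accuracy": correct / len(truth) if truth else 1.0,
        "per_mode": per_mode,
        "confusion": confusion,
    }
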