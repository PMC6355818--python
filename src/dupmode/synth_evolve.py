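"""Forward simulator of gene-family expansion with known ground truth.

Starting from a single multi-exon ancestor gene on a multi-chromosome
random genome, the simulator applies one duplication event per step --
tandem (full genomic copy inserted a short distance downstream of the
donor), segmental (full genomic copy on a different chromosome) or retro
(spliced CDS copy, intronless, with an appended poly(A) tract and a
target-site duplication flanking the insert) -- then evolves every family
gene by Jukes-Cantor-style substitutions. Unrelated "decoy" genes are
annotated over the random background at a realistic density so that
family harvesting and the intervening-gene rule of tandem chaining are
both exercised. The output is FASTA + GFF3 + an event-truth table, so
every pipeline stage can be scored against planted truth.

Conventions: family genes live on the + strand; duplication copies are
instantaneous and complete (the gene span only -- promoters, poly(A)
tracts and target-site duplications of the donor are not copied, which is
what lets flank evidence pinpoint true retrocopies); copies insert
downstream of their donor. Deterministic given the seed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .genome_io import GeneModel, SeqRecord
from .promoter_scan import load_element_table

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
           if a + b + c not in _STOPS]

#: margin kept clear around family genes so insertions never disturb the
#: 1 kb flanks the retro scans read
_FLANK_MARGIN = 1100


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated expansion history."""

    seed: int
    n_chromosomes: int = 8
    chrom_len_bp: int = 1_000_000
    ancestor_exon_lengths: tuple[int, ...] = (300, 150, 300)
    ancestor_intron_lengths: tuple[int, ...] = (200, 200)
    n_events: int = 12
    event_type_counts: tuple[int, int, int] | None = (4, 4, 4)
    event_type_probs: tuple[float, float, float] | None = None
    subs_rate_per_site_per_step: float = 0.01
    polyA_len: int = 15
    tsd_len: int = 10
    flank_erosion_rate: float = 0.0
    independent_intron_loss_prob: float = 0.0
    decoy_gene_spacing_bp: int = 20_000
    decoy_gene_len_bp: int = 600
    promoter_elements_to_plant: tuple[tuple[str, int], ...] = (
        ("G-box", 1), ("LTR", 1), ("TCT-motif", 2))

    def __post_init__(self) -> None:
        if self.event_type_probs is not None:
            if any(p < 0 or p > 1 for p in self.event_type_probs) or \
                    abs(sum(self.event_type_probs) - 1.0) > 1e-9:
                raise SimulationError("event type probabilities must be in "
                                      "[0,1] and sum to 1")
        elif self.event_type_counts is not None:
            if sum(self.event_type_counts) != self.n_events:
                raise SimulationError("event type counts must sum to n_events")
        else:
            raise SimulationError("need event_type_counts or event_type_probs")
        if self.subs_rate_per_site_per_step < 0 or self.flank_erosion_rate < 0:
            raise SimulationError("substitution rates must be >= 0")
        if self.polyA_len < 0 or self.tsd_len < 0:
            raise SimulationError("polyA_len and tsd_len must be >= 0")
        if len(self.ancestor_intron_lengths) != \
                len(self.ancestor_exon_lengths) - 1:
            raise SimulationError("need one intron length per exon junction")


@dataclass
class EventRecord:
    event_id: str
    step: int
    type: str               # tandem | segmental | retro
    donor_gene_id: str
    new_gene_id: str
    chrom: str
    position: int           # 1-based start of the new gene


@dataclass
class _SimGene:
    gene_id: str
    chrom_idx: int
    start: int              # 1-based inclusive
    end: int
    strand: str
    exon_offsets: tuple[tuple[int, int], ...]   # 0-based, relative to start
    family: bool


@dataclass
class SimulatedDataset:
    genome: list[SeqRecord]
    models: list[GeneModel]
    truth: list[EventRecord]
    parent: dict[str, str]
    query_id: str
    family_ids: list[str]
    homoplasy_intron_losses: list[str]
    true_tree_newick: str
    config: SimConfig


# ------------------------------------------------------------ mutation

def _mutate_array(arr: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """In-place uniform substitution of a uint8 ACGT array."""
    if rate == 0 or arr.size == 0:
        return
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size == 0:
        return
    idx = _BASE_INDEX[arr[hit]]
    shift = rng.integers(1, 4, size=hit.size)
    arr[hit] = _BASES[(idx + shift) % 4]


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``rate``,
    replacement uniform over the three alternative bases."""
    if rate < 0 or rate > 1:
        raise SimulationError(f"substitution rate {rate} outside [0, 1]")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    if np.any(_BASE_INDEX[arr] == 255):
        raise SimulationError("mutate expects pure ACGT sequence")
    _mutate_array(arr, rate, rng)
    return arr.tobytes().decode()


# ------------------------------------------------------------ simulator

class _Sim:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.chroms: list[np.ndarray] = []
        self.genes: list[_SimGene] = []
        self.truth: list[EventRecord] = []
        self.parent: dict[str, str] = {}
        self.homoplasy: list[str] = []
        self.lineage: dict[str, dict] = {}   # leaf label -> tree node
        self.tree_root: dict | None = None

    # -- setup ---------------------------------------------------------
    def build_background(self) -> None:
        for _ in range(self.cfg.n_chromosomes):
            self.chroms.append(
                self.rng.choice(_BASES, size=self.cfg.chrom_len_bp))

    def build_ancestor(self) -> None:
        cfg = self.cfg
        n_codons = sum(cfg.ancestor_exon_lengths) // 3
        body = ["ATG"] + [ _CODONS[i] for i in
                           self.rng.integers(0, len(_CODONS), n_codons - 2)
                         ] + ["TAA"]
        cds = "".join(body)
        pieces, exon_offsets, off, cpos = [], [], 0, 0
        for i, elen in enumerate(cfg.ancestor_exon_lengths):
            pieces.append(cds[cpos:cpos + elen])
            exon_offsets.append((off, off + elen - 1))
            cpos += elen
            off += elen
            if i < len(cfg.ancestor_intron_lengths):
                ilen = cfg.ancestor_intron_lengths[i]
                intron = ("GT"
                          + "".join("ACGT"[j] for j in
                                    self.rng.integers(0, 4, ilen - 4))
                          + "AG")
                pieces.append(intron)
                off += ilen
        gene_seq = "".join(pieces)
        start = 100_001
        arr = np.frombuffer(gene_seq.encode(), dtype=np.uint8)
        self.chroms[0][start - 1:start - 1 + arr.size] = arr
        gene = _SimGene("fam00", 0, start, start + arr.size - 1, "+",
                        tuple(exon_offsets), family=True)
        self.genes.append(gene)
        node = {"label": "fam00"}
        self.lineage["fam00"] = node
        self.tree_root = node

    def build_decoys(self) -> None:
        cfg = self.cfg
        k = 0
        for ci in range(cfg.n_chromosomes):
            pos = cfg.decoy_gene_spacing_bp
            while pos + cfg.decoy_gene_len_bp < cfg.chrom_len_bp - 2000:
                start = int(pos + self.rng.integers(
                    0, cfg.decoy_gene_spacing_bp // 2))
                end = start + cfg.decoy_gene_len_bp - 1
                clear = all(not (start - _FLANK_MARGIN <= g.end and
                                 g.start - _FLANK_MARGIN <= end)
                            for g in self.genes if g.chrom_idx == ci)
                if clear and end < len(self.chroms[ci]):
                    k += 1
                    self.genes.append(_SimGene(
                        f"dec{k:03d}", ci, start, end,
                        "+" if k % 2 else "-",
                        ((0, cfg.decoy_gene_len_bp - 1),), family=False))
                pos += cfg.decoy_gene_spacing_bp
        log.debug("planted %d decoy genes", k)

    # -- genome surgery ------------------------------------------------
    def _insert(self, ci: int, pos_after: int, segment: np.ndarray) -> None:
        c = self.chroms[ci]
        self.chroms[ci] = np.concatenate([c[:pos_after], segment,
                                          c[pos_after:]])
        for g in self.genes:
            if g.chrom_idx == ci and g.start > pos_after:
                g.start += segment.size
                g.end += segment.size

    def _delete(self, ci: int, start: int, end: int) -> None:
        """Remove 1-based inclusive [start, end] from chromosome ci."""
        c = self.chroms[ci]
        self.chroms[ci] = np.concatenate([c[:start - 1], c[end:]])
        length = end - start + 1
        for g in self.genes:
            if g.chrom_idx == ci and g.start > end:
                g.start -= length
                g.end -= length

    def _site_ok(self, ci: int, pos_after: int, span: int) -> bool:
        lo, hi = pos_after, pos_after + span   # bases [lo+1, hi] touched
        if lo < _FLANK_MARGIN or hi + _FLANK_MARGIN > len(self.chroms[ci]):
            return False
        for g in self.genes:
            if g.chrom_idx != ci:
                continue
            margin = _FLANK_MARGIN if g.family else 0
            if lo + 1 <= g.end + margin and g.start - margin <= hi:
                return False
        return True

    def _find_site(self, ci: int, desired: int, span: int) -> int:
        """Directed placement: first clear position at/after ``desired``
        (tandem copies slide past existing array members). If the donor
        sits too close to the chromosome end for any downstream site, the
        copy is placed upstream instead (unequal crossing-over can yield
        either orientation); only then is the chromosome declared full."""
        pos = max(desired, _FLANK_MARGIN)
        limit = len(self.chroms[ci]) - span - _FLANK_MARGIN
        while pos <= limit:
            if self._site_ok(ci, pos, span):
                return pos
            pos += 250
        pos = min(desired, limit)
        while pos >= _FLANK_MARGIN:
            if self._site_ok(ci, pos, span):
                return pos
            pos -= 250
        raise SimulationError(
            f"impossible placement: chromosome {ci + 1} is full")

    def _find_site_random(self, ci: int, span: int) -> int:
        """Uniform random placement by rejection sampling, so insertion
        loci carry no positional bias toward existing genes."""
        limit = len(self.chroms[ci]) - span - _FLANK_MARGIN
        if limit <= _FLANK_MARGIN:
            raise SimulationError(
                f"impossible placement: chromosome {ci + 1} is full")
        for _ in range(500):
            pos = int(self.rng.integers(_FLANK_MARGIN, limit))
            if self._site_ok(ci, pos, span):
                return pos
        raise SimulationError(
            f"impossible placement: chromosome {ci + 1} is full")

    def _gene_seq(self, g: _SimGene) -> np.ndarray:
        return self.chroms[g.chrom_idx][g.start - 1:g.end].copy()

    def _gene_cds(self, g: _SimGene) -> np.ndarray:
        body = self.chroms[g.chrom_idx][g.start - 1:g.end]
        return np.concatenate([body[s:e + 1] for s, e in g.exon_offsets])

    def _split_lineage(self, donor: str, new: str) -> None:
        node = self.lineage[donor]
        left = {"label": donor}
        right = {"label": new}
        node.pop("label", None)
        node["children"] = [left, right]
        self.lineage[donor] = left
        self.lineage[new] = right

    # -- events --------------------------------------------------------
    def apply_event(self, step: int, etype: str, donor: _SimGene,
                    new_id: str) -> EventRecord:
        cfg = self.cfg
        if etype == "tandem":
            gap = int(self.rng.integers(1500, 8001))
            seg = self._gene_seq(donor)
            pos = self._find_site(donor.chrom_idx, donor.end + gap, seg.size)
            self._insert(donor.chrom_idx, pos, seg)
            gene = _SimGene(new_id, donor.chrom_idx, pos + 1, pos + seg.size,
                            "+", donor.exon_offsets, family=True)
        elif etype == "segmental":
            others = [i for i in range(cfg.n_chromosomes)
                      if i != donor.chrom_idx]
            ci = int(self.rng.choice(others))
            seg = self._gene_seq(donor)
            pos = self._find_site_random(ci, seg.size)
            self._insert(ci, pos, seg)
            gene = _SimGene(new_id, ci, pos + 1, pos + seg.size, "+",
                            donor.exon_offsets, family=True)
        elif etype == "retro":
            ci = int(self.rng.integers(0, cfg.n_chromosomes))
            cds = self._gene_cds(donor)
            polyA = np.frombuffer(b"A" * cfg.polyA_len, dtype=np.uint8)
            pos = self._find_site_random(ci, cds.size + cfg.tsd_len)
            tsd = self.chroms[ci][pos:pos + cfg.tsd_len].copy()
            seg = np.concatenate([cds, polyA, tsd])
            self._insert(ci, pos + cfg.tsd_len, seg)
            gene = _SimGene(new_id, ci, pos + cfg.tsd_len + 1,
                            pos + cfg.tsd_len + cds.size, "+",
                            ((0, cds.size - 1),), family=True)
        else:
            raise SimulationError(f"unknown event type {etype!r}")
        self.genes.append(gene)
        self.parent[new_id] = donor.gene_id
        self._split_lineage(donor.gene_id, new_id)
        return EventRecord(f"E{step:02d}", step, etype, donor.gene_id,
                           new_id, f"LG{gene.chrom_idx + 1}", gene.start)

    def evolve_step(self) -> None:
        rate = self.cfg.subs_rate_per_site_per_step
        for g in self.genes:
            if g.family:
                _mutate_array(self.chroms[g.chrom_idx][g.start - 1:g.end],
                              rate, self.rng)
        p_loss = self.cfg.independent_intron_loss_prob
        if p_loss > 0:
            for g in list(self.genes):
                if g.family and len(g.exon_offsets) > 1 \
                        and self.rng.random() < p_loss:
                    self._lose_introns(g)

    def _lose_introns(self, g: _SimGene) -> None:
        """Homoplasy stressor: splice a gene down to its CDS in place."""
        cds = self._gene_cds(g)
        start = g.start
        self._delete(g.chrom_idx, g.start, g.end)
        self._insert(g.chrom_idx, start - 1, cds)
        g.start = start  # _insert shifted this record along with the rest
        g.end = start + cds.size - 1
        g.exon_offsets = ((0, cds.size - 1),)
        self.homoplasy.append(g.gene_id)
        log.debug("independent intron loss in %s", g.gene_id)

    # -- finalisation --------------------------------------------------
    def plant_promoters(self) -> None:
        wanted = list(self.cfg.promoter_elements_to_plant)
        if not wanted:
            return
        table = {el.name: el for el in load_element_table()}
        for name, _count in wanted:
            if name not in table:
                raise SimulationError(f"unknown promoter element {name!r}")
        for g in [g for g in self.genes if g.family]:
            used: list[tuple[int, int]] = []
            for name, count in wanted:
                patterns = table[name].expanded()
                for _ in range(count):
                    pat = patterns[int(self.rng.integers(0, len(patterns)))]
                    placed = False
                    for _try in range(20):
                        off = int(self.rng.integers(200 + len(pat), 1001))
                        s = g.start - off                     # 1-based start
                        e = s + len(pat) - 1
                        if s < 1:
                            continue
                        if any(s <= ue and us <= e for us, ue in used):
                            continue
                        arr = np.frombuffer(pat.encode(), dtype=np.uint8)
                        self.chroms[g.chrom_idx][s - 1:e] = arr
                        used.append((s, e))
                        placed = True
                        break
                    if not placed:
                        log.warning("could not place %s upstream of %s",
                                    name, g.gene_id)

    def erode_flanks(self) -> None:
        rate = self.cfg.flank_erosion_rate
        if rate == 0:
            return
        for g in [g for g in self.genes if g.family]:
            c = self.chroms[g.chrom_idx]
            lo = max(0, g.start - 1001)
            _mutate_array(c[lo:g.start - 1], rate, self.rng)
            hi = min(len(c), g.end + 1000)
            _mutate_array(c[g.end:hi], rate, self.rng)

    def _newick(self) -> str:
        def render(node: dict) -> str:
            if "children" in node:
                inner = ",".join(render(c) for c in node["children"])
                return f"({inner}):1"
            return f"{node['label']}:1"
        body = render(self.tree_root)
        return body.rsplit(":", 1)[0] + ";"

    def dataset(self) -> SimulatedDataset:
        genome = [SeqRecord(f"LG{i + 1}", c.tobytes().decode())
                  for i, c in enumerate(self.chroms)]
        models = []
        for g in self.genes:
            models.append(GeneModel(
                gene_id=g.gene_id, chrom=f"LG{g.chrom_idx + 1}",
                strand=g.strand, start=g.start, end=g.end,
                exons=tuple((g.start + s, g.start + e)
                            for s, e in g.exon_offsets),
                source_tag="sim_family" if g.family else "sim_decoy"))
        models.sort(key=lambda m: (m.chrom, m.start, m.gene_id))
        return SimulatedDataset(
            genome=genome, models=models, truth=list(self.truth),
            parent=dict(self.parent), query_id="fam00",
            family_ids=[g.gene_id for g in self.genes if g.family],
            homoplasy_intron_losses=list(self.homoplasy),
            true_tree_newick=self._newick(), config=self.cfg)


def simulate(config: SimConfig) -> SimulatedDataset:
    """Run the forward simulation; deterministic given ``config.seed``."""
    sim = _Sim(config)
    sim.build_background()
    sim.build_ancestor()
    sim.build_decoys()
    if config.event_type_probs is not None:
        types = [("tandem", "segmental", "retro")[
            int(sim.rng.choice(3, p=config.event_type_probs))]
            for _ in range(config.n_events)]
    else:
        types = (["tandem"] * config.event_type_counts[0]
                 + ["segmental"] * config.event_type_counts[1]
                 + ["retro"] * config.event_type_counts[2])
        sim.rng.shuffle(types)
    for step, etype in enumerate(types, 1):
        family = [g for g in sim.genes if g.family]
        donor = family[int(sim.rng.integers(0, len(family)))]
        new_id = f"fam{step:02d}"
        sim.truth.append(sim.apply_event(step, etype, donor, new_id))
        sim.evolve_step()
    sim.plant_promoters()
    sim.erode_flanks()
    return sim.dataset()


# ------------------------------------------------------------- truth I/O

_TRUTH_COLS = ["event_id", "step", "type", "donor_gene_id", "new_gene_id",
               "chrom", "position"]


def write_truth(dataset_or_records, path) -> None:
    records = (dataset_or_records.truth
               if isinstance(dataset_or_records, SimulatedDataset)
               else dataset_or_records)
    with open(path, "w", newline="\n") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TRUTH_COLS)
        for r in records:
            w.writerow([r.event_id, r.step, r.type, r.donor_gene_id,
                        r.new_gene_id, r.chrom, r.position])


def read_truth(path) -> list[EventRecord]:
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(EventRecord(
                event_id=row["event_id"], step=int(row["step"]),
                type=row["type"], donor_gene_id=row["donor_gene_id"],
                new_gene_id=row["new_gene_id"], chrom=row["chrom"],
                position=int(row["position"])))
    return out
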