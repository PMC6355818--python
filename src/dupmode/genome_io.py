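"""Sequence and annotation I/O.

Reads/writes FASTA and GFF3 and derives per-gene sequences (CDS, protein,
1 kb flanks) in gene-strand orientation. All genomic coordinates are GFF3
style: 1-based, inclusive at both ends. Flanks are reported in transcription
direction, so ``flank3`` always begins immediately after the stop codon
regardless of strand -- the orientation the poly(A)/TSD scans rely on.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from Bio.Data import CodonTable

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY" + "X*")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


class GenomeIOError(ValueError):
    """Malformed FASTA/GFF3 input or inconsistent gene model."""


@dataclass(frozen=True)
class SeqRecord:
    """A named uppercase sequence (DNA or protein)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise GenomeIOError("sequence record with empty id")
        object.__setattr__(self, "seq", self.seq.upper())


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: span, strand and ordered exon blocks.

    ``exons`` are (start, end) pairs, 1-based inclusive, sorted by
    coordinate, non-overlapping and contained in [start, end].
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    source_tag: str = "dupmode"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise GenomeIOError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if self.start > self.end:
            raise GenomeIOError(f"{self.gene_id}: start > end")
        if not self.exons:
            raise GenomeIOError(f"{self.gene_id}: gene without exons")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        prev_end = None
        for s, e in exons:
            if s > e:
                raise GenomeIOError(f"{self.gene_id}: exon with start > end ({s}>{e})")
            if s < self.start or e > self.end:
                raise GenomeIOError(f"{self.gene_id}: exon ({s},{e}) outside gene span")
            if prev_end is not None and s <= prev_end:
                raise GenomeIOError(f"{self.gene_id}: overlapping exons")
            prev_end = e
        object.__setattr__(self, "exons", exons)

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1


@dataclass
class GeneSequences:
    """Derived sequences for one gene, all in gene-strand orientation."""

    gene_id: str
    cds: str
    protein: str
    flank5: str
    flank3: str
    flank5_clipped: bool = False
    flank3_clipped: bool = False
    internal_stop: bool = False


@dataclass
class TranslationResult:
    protein: str
    internal_stop: bool = False


# ---------------------------------------------------------------- FASTA

def parse_fasta(path: str | Path | io.TextIOBase) -> list[SeqRecord]:
    """Parse a FASTA file into uppercase records, preserving file order."""
    handle = path if isinstance(path, io.TextIOBase) else open(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise GenomeIOError(f"duplicate FASTA id: {rec.id}")
            seen.add(rec.id)
            seq = str(rec.seq).upper()
            if not seq:
                raise GenomeIOError(f"empty sequence for FASTA id: {rec.id}")
            records.append(SeqRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write records 60 columns wide, UTF-8, LF line endings."""
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(bio, fh, "fasta")


# ----------------------------------------------------------------- GFF3

def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def parse_gff3(path: str | Path | io.TextIOBase) -> list[GeneModel]:
    """Parse gene/mRNA/exon (or CDS) features into GeneModels.

    Exons are collated under their gene, walking mRNA parents where present.
    Genes lacking exon features fall back to CDS features, then to the gene
    span as a single exon. Result sorted by (chrom, start).
    """
    handle = path if isinstance(path, io.TextIOBase) else open(path)
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    blocks: dict[str, dict[str, list[tuple[int, int]]]] = {}
    order: list[str] = []
    with handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeIOError(f"malformed GFF3 line: {line!r}")
            chrom, source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = cols
            start, end = int(start_s), int(end_s)
            attrs = _parse_attributes(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if not gid:
                    raise GenomeIOError(f"gene feature without ID: {line!r}")
                if gid in genes:
                    raise GenomeIOError(f"duplicate gene id: {gid}")
                genes[gid] = dict(chrom=chrom, strand=strand, start=start,
                                  end=end, source=source)
                order.append(gid)
            elif ftype == "mRNA":
                parent = attrs.get("Parent")
                mid = attrs.get("ID")
                if mid and parent:
                    mrna_parent[mid] = parent
            elif ftype in {"exon", "CDS"}:
                parent = attrs.get("Parent")
                if parent is None:
                    raise GenomeIOError(f"{ftype} feature without Parent: {line!r}")
                gid = mrna_parent.get(parent, parent)
                blocks.setdefault(gid, {}).setdefault(ftype, []).append((start, end))
    models = []
    for gid in order:
        info = genes[gid]
        gene_blocks = blocks.get(gid, {})
        exons = gene_blocks.get("exon") or gene_blocks.get("CDS") or [
            (info["start"], info["end"])
        ]
        models.append(GeneModel(
            gene_id=gid, chrom=info["chrom"], strand=info["strand"],
            start=info["start"], end=info["end"],
            exons=tuple(sorted(exons)), source_tag=info["source"],
        ))
    models.sort(key=lambda m: (m.chrom, m.start, m.gene_id))
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene + mRNA + exon features with a ##gff-version 3 header."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.chrom, m.start, m.gene_id)):
            base = f"{m.chrom}\t{m.source_tag}"
            fh.write(f"{base}\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                     f"ID={m.gene_id}\n")
            mid = f"{m.gene_id}.t1"
            fh.write(f"{base}\tmRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                     f"ID={mid};Parent={m.gene_id}\n")
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(f"{base}\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                         f"ID={mid}.exon{i};Parent={mid}\n")


# ---------------------------------------------------- sequence derivation

def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(cds: str) -> TranslationResult:
    """Translate a CDS with the standard code.

    The terminal stop codon is dropped; internal stops are kept as '*' and
    flagged; any codon containing N yields 'X' (tolerant of draft assemblies).
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise GenomeIOError(f"CDS length {len(cds)} not divisible by 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in _STANDARD_TABLE.stop_codons:
        codons = codons[:-1]
    aa = []
    internal_stop = False
    for codon in codons:
        if codon in _STANDARD_TABLE.stop_codons:
            aa.append("*")
            internal_stop = True
        elif codon in _STANDARD_TABLE.forward_table:
            aa.append(_STANDARD_TABLE.forward_table[codon])
        elif set(codon) - set("ACGT"):
            aa.append("X")
        else:  # unreachable for the ACGTN alphabet, kept defensive
            aa.append("X")
    return TranslationResult("".join(aa), internal_stop)


def extract_gene_sequences(
    genome: list[SeqRecord],
    model: GeneModel,
    flank_bp: int = 1000,
    translate_cds: bool = True,
) -> GeneSequences:
    """Derive CDS, protein and flanks for one gene model.

    CDS is the exon concatenation, reverse-complemented on the minus strand.
    Flanks are clipped at contig edges (flagged) and oriented so that
    ``flank3`` starts just downstream of the gene in transcription direction.
    """
    by_id = {r.id: r for r in genome}
    if model.chrom not in by_id:
        raise GenomeIOError(f"{model.gene_id}: chromosome {model.chrom} not in genome")
    chrom_seq = by_id[model.chrom].seq
    if model.end > len(chrom_seq):
        raise GenomeIOError(
            f"{model.gene_id}: model extends past contig end "
            f"({model.end} > {len(chrom_seq)})")
    cds = "".join(chrom_seq[s - 1:e] for s, e in model.exons)
    up_start = max(1, model.start - flank_bp)
    upstream = chrom_seq[up_start - 1:model.start - 1]
    down_end = min(len(chrom_seq), model.end + flank_bp)
    downstream = chrom_seq[model.end:down_end]
    up_clipped = model.start - flank_bp < 1
    down_clipped = model.end + flank_bp > len(chrom_seq)
    if model.strand == "-":
        cds = reverse_complement(cds)
        flank5, flank3 = reverse_complement(downstream), reverse_complement(upstream)
        f5_clip, f3_clip = down_clipped, up_clipped
    else:
        flank5, flank3 = upstream, downstream
        f5_clip, f3_clip = up_clipped, down_clipped
    protein = ""
    internal_stop = False
    if translate_cds and len(cds) % 3 == 0:
        tr = translate(cds)
        protein, internal_stop = tr.protein, tr.internal_stop
    return GeneSequences(
        gene_id=model.gene_id, cds=cds, protein=protein,
        flank5=flank5, flank3=flank3,
        flank5_clipped=f5_clip, flank3_clipped=f3_clip,
        internal_stop=internal_stop,
    )
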