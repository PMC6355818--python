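"""Pairwise alignment, similarity statistics and family harvesting.

The family is harvested by aligning a query protein against every candidate
(the in-silico analogue of a BLASTP sweep with the reference acyltransferase
as query) and keeping hits below an E-value cutoff. Alignment scores come
from affine-gap dynamic programming (``Bio.Align.PairwiseAligner``); E-values
use the ungapped Karlin-Altschul form E = K*m*n*exp(-lambda*S) with published
per-matrix constants, an explicit approximation of gapped BLAST statistics.

Scoring conventions
-------------------
A gap of length L scores ``gap_open + L * gap_extend`` (BLAST style, both
terms <= 0). Percent identity uses the full alignment length, gap columns
included, matching BLAST's "identities / alignment length".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import DNA_ALPHABET, SeqRecord

#: Ungapped Karlin-Altschul constants per scoring system.
KARLIN_CONSTANTS = {
    "BLOSUM62": (0.3176, 0.134),
    "DNA_1_-2": (1.33, 0.621),
}


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class KarlinParams:
    lam: float
    k: float

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.k <= 0:
            raise AlignmentError("Karlin parameters lambda and K must be positive")


@dataclass(frozen=True)
class AlignParams:
    """Alignment mode and scoring.

    ``substitution_matrix`` is a named protein matrix (e.g. "BLOSUM62") or
    None for DNA match/mismatch scoring.
    """

    mode: str = "local"
    substitution_matrix: str | None = "BLOSUM62"
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -11.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.mode not in {"local", "global"}:
            raise AlignmentError(f"unknown alignment mode {self.mode!r}")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise AlignmentError("require gap_open <= gap_extend <= 0")

    @property
    def is_protein(self) -> bool:
        return self.substitution_matrix is not None

    def karlin(self) -> KarlinParams:
        key = self.substitution_matrix or f"DNA_{self.match:g}_{self.mismatch:g}"
        lam, k = KARLIN_CONSTANTS.get(key, KARLIN_CONSTANTS["BLOSUM62"])
        return KarlinParams(lam, k)


#: BLAST-flavoured defaults: BLOSUM62 -11/-1 for proteins,
#: +1/-2 with -5/-2 gaps for DNA.
PROTEIN_PARAMS = AlignParams(mode="local", substitution_matrix="BLOSUM62",
                             gap_open=-11.0, gap_extend=-1.0)
DNA_PARAMS = AlignParams(mode="local", substitution_matrix=None,
                         match=1.0, mismatch=-2.0, gap_open=-5.0, gap_extend=-2.0)


@dataclass
class AlignmentResult:
    query_id: str
    subject_id: str
    score: float
    aligned_cols: int
    matches: int
    mismatches: int
    gap_cols: int
    identity_pct: float
    evalue: float = math.inf

    def __post_init__(self) -> None:
        assert self.matches + self.mismatches + self.gap_cols == self.aligned_cols


def _looks_like_dna(seq: str) -> bool:
    return bool(seq) and set(seq) <= DNA_ALPHABET


def _check_alphabets(a: str, b: str, params: AlignParams) -> None:
    if not a or not b:
        raise AlignmentError("cannot align empty sequences")
    if _looks_like_dna(a) != _looks_like_dna(b) and params.is_protein is False:
        raise AlignmentError("mixed DNA/protein alphabets")
    if not params.is_protein:
        for seq in (a, b):
            if not set(seq) <= DNA_ALPHABET:
                raise AlignmentError("non-DNA characters under DNA scoring")


def _dna_matrix(match: float, mismatch: float):
    alphabet = "ACGTN"
    m = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            if "N" in (x, y):
                m[x, y] = 0.0  # N is neutral, tolerant of draft assemblies
            else:
                m[x, y] = match if x == y else mismatch
    return m


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = params.mode
    if params.is_protein:
        aligner.substitution_matrix = substitution_matrices.load(
            params.substitution_matrix)
    else:
        aligner.substitution_matrix = _dna_matrix(params.match, params.mismatch)
    # internal convention: a length-L gap costs gap_open + L*gap_extend
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner


def pairwise_align(a: SeqRecord | str, b: SeqRecord | str,
                   params: AlignParams = PROTEIN_PARAMS,
                   compute_evalue: bool = False) -> AlignmentResult:
    """Optimal affine-gap alignment of two sequences.

    Returns the optimal score together with column counts taken from the
    aligner's canonical (deterministic) first traceback. In local mode two
    unrelatable sequences yield the empty alignment with score 0.
    """
    qid, query = (a.id, a.seq) if isinstance(a, SeqRecord) else ("query", a)
    sid, subject = (b.id, b.seq) if isinstance(b, SeqRecord) else ("subject", b)
    _check_alphabets(query, subject, params)
    aligner = _make_aligner(params)
    score = aligner.score(query, subject)
    if params.mode == "local" and score <= 0:
        result = AlignmentResult(qid, sid, 0.0, 0, 0, 0, 0, 0.0)
    else:
        aln = aligner.align(query, subject)[0]
        rows = (str(aln[0]), str(aln[1]))
        matches = mismatches = gap_cols = 0
        for x, y in zip(*rows):
            if x == "-" or y == "-":
                gap_cols += 1
            elif x == y:
                matches += 1
            else:
                mismatches += 1
        cols = matches + mismatches + gap_cols
        ident = 100.0 * matches / cols if cols else 0.0
        result = AlignmentResult(qid, sid, float(score), cols, matches,
                                 mismatches, gap_cols, ident)
    if compute_evalue:
        result.evalue = evalue(result.score, len(query), len(subject),
                               params.karlin())
    return result


def percent_identity(r: AlignmentResult, include_gaps: bool = True) -> float:
    """100 * matches / columns; gap columns in the denominator by default."""
    denom = r.aligned_cols if include_gaps else (r.matches + r.mismatches)
    if denom <= 0:
        raise AlignmentError("percent identity of an empty alignment is undefined")
    return 100.0 * r.matches / denom


def evalue(score: float, m: int, n: int, karlin: KarlinParams) -> float:
    """Ungapped Karlin-Altschul expectation E = K*m*n*exp(-lambda*S)."""
    if not math.isfinite(score):
        raise AlignmentError("non-finite alignment score")
    if m < 1 or n < 1:
        raise AlignmentError("sequence lengths must be >= 1")
    return karlin.k * m * n * math.exp(-karlin.lam * score)


def find_family(query: SeqRecord, proteome: list[SeqRecord],
                params: AlignParams = PROTEIN_PARAMS,
                max_evalue: float = 1e-10,
                min_score: float | None = None,
                ) -> list[tuple[SeqRecord, AlignmentResult]]:
    """Harvest family members: query-vs-all alignment, threshold, sort.

    Hits pass when E-value <= ``max_evalue`` (and score >= ``min_score`` if
    given); results are sorted by descending score then subject id. The
    query's self-hit is retained when the query is in the collection.
    """
    if not proteome:
        raise AlignmentError("empty proteome")
    hits = []
    for rec in proteome:
        if not rec.seq:
            continue
        r = pairwise_align(query, rec, params, compute_evalue=True)
        if r.evalue <= max_evalue and (min_score is None or r.score >= min_score):
            hits.append((rec, r))
    hits.sort(key=lambda pair: (-pair[1].score, pair[0].id))
    return hits


def write_hit_table(hits, path) -> None:
    """BLAST outfmt-6-like TSV (raw score in place of a bitscore)."""
    cols = "qseqid sseqid pident length mismatch gapopen evalue score".split()
    with open(path, "w", newline="\n") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for rec, r in hits:
            fh.write("\t".join([
                r.query_id, r.subject_id, f"{r.identity_pct:.2f}",
                str(r.aligned_cols), str(r.mismatches), str(r.gap_cols),
                f"{r.evalue:.3g}", f"{r.score:g}",
            ]) + "\n")


# -------------------------------------------------- evolutionary distances

def p_distance(a: str, b: str, params: AlignParams | None = None) -> float:
    """Proportion of differing sites over ungapped columns of a global
    alignment (gapped columns dropped pairwise)."""
    if params is None:
        params = replace(PROTEIN_PARAMS, mode="global")
    elif params.mode != "global":
        params = replace(params, mode="global")
    r = pairwise_align(a, b, params)
    compared = r.matches + r.mismatches
    if compared == 0:
        raise AlignmentError("no comparable (ungapped) columns")
    return r.mismatches / compared


def poisson_correct(p: float) -> float:
    """Multiple-hit correction of a p-distance: d = -ln(1 - p)."""
    if not 0.0 <= p < 1.0:
        raise AlignmentError(f"Poisson correction undefined for p={p}")
    return -math.log1p(-p)


def poisson_distance_matrix(records: list[SeqRecord],
                            params: AlignParams | None = None):
    """Labels plus the symmetric Poisson-corrected distance matrix."""
    labels = [r.id for r in records]
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = poisson_correct(
                p_distance(records[i].seq, records[j].seq, params))
    return labels, d
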