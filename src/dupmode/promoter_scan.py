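"""Promoter cis-element scanning.

A fixed dictionary of light- and temperature-responsive promoter elements
(G-box, LTR, HSE, Sp1, ...) is matched exactly against promoter DNA, with
degenerate alternatives expanded to literal patterns and both strands
scanned by default (strand-agnostic, as PlantCARE reports elements). Every
occurrence is reported, overlaps allowed; palindromic patterns are counted
once per position.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .genome_io import reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class PromoterScanError(ValueError):
    pass


@dataclass(frozen=True)
class CisElement:
    """A named promoter motif with literal/degenerate alternatives."""

    name: str
    sequences: tuple[str, ...]
    function: str = ""

    def expanded(self) -> tuple[str, ...]:
        """All literal DNA patterns this element matches."""
        out: list[str] = []
        for pat in self.sequences:
            out.extend(_expand_pattern(pat, self.name))
        # stable dedup
        seen, uniq = set(), []
        for p in out:
            if p not in seen:
                seen.add(p)
                uniq.append(p)
        return tuple(uniq)


def _expand_pattern(pattern: str, name: str) -> list[str]:
    """Expand ``(G/A)`` alternative groups and IUPAC codes to literals."""
    if not pattern:
        raise PromoterScanError(f"element {name!r}: empty pattern")
    # tokenize: parenthesised alternative groups or single letters
    tokens: list[list[str]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "(":
            j = pattern.find(")", i)
            if j < 0:
                raise PromoterScanError(
                    f"element {name!r}: unclosed group in {pattern!r}")
            alts = pattern[i + 1:j].split("/")
            if not all(alts) or len(alts) < 2:
                raise PromoterScanError(
                    f"element {name!r}: malformed group in {pattern!r}")
            tokens.append(alts)
            i = j + 1
        else:
            up = ch.upper()
            if up not in IUPAC:
                raise PromoterScanError(
                    f"element {name!r}: bad character {ch!r} in {pattern!r}")
            tokens.append(list(IUPAC[up]))
            i += 1
    literals = [""]
    for alts in tokens:
        literals = [lit + a.upper() for lit in literals for a in alts]
    return literals


#: The built-in dictionary: every element/sequence row of the reference
#: promoter survey, collated across the three surveyed promoters.
DEFAULT_ELEMENTS: tuple[CisElement, ...] = (
    CisElement("5' UTR Py-rich stretch", ("TTTCTTCTCT", "TTTCTCTCTCTCTC"),
               "Cis-acting element conferring high transcription levels"),
    CisElement("AE-box", ("AGAAACAA",), "Part of a module for light response"),
    CisElement("AT1-motif", ("AATTATTTTTTATT",),
               "Part of a light-responsive module"),
    CisElement("ATCT-motif", ("AATCTGATCG",),
               "Part of a conserved DNA module involved in light responsiveness"),
    CisElement("Box 4", ("ATTAAT",),
               "Part of a conserved DNA module involved in light responsiveness"),
    CisElement("Box I", ("TTTCAAA",), "Light-responsive element"),
    CisElement("CATT-motif", ("GCATTC",), "Part of a light-responsive element"),
    CisElement("G-box",
               ("CACGTG", "CACACATGGAA", "CACGTA", "TACGTG", "CACGAC",
                "GACACGTAGT"),
               "Cis-acting regulatory element involved in light responsiveness"),
    CisElement("GA-motif", ("AAAGATGA",), "Part of a light-responsive element"),
    CisElement("GAG-motif", ("GGAGATG", "AGAGAGT"),
               "Part of a light-responsive element"),
    CisElement("GATA-motif", ("GATAGGG",), "Part of a light-responsive element"),
    CisElement("GT1-motif", ("GGTTAA", "AATCCACA"), "Light-responsive element"),
    CisElement("GTGGC-motif", ("GATTCTGTGGC",),
               "Part of a light-responsive element"),
    CisElement("Gap-box", ("AAATGGAGA",), "Part of a light-responsive element"),
    CisElement("HSE", ("AAAAAATTTC", "AGAAAATTCG"),
               "Cis-acting element involved in heat-stress responsiveness"),
    CisElement("I-box", ("GATAGGG",), "Part of a light-responsive element"),
    CisElement("L-box", ("ATCCCACCTAC",), "Part of a light-responsive element"),
    CisElement("LTR", ("CCGAAA",),
               "Cis-acting element involved in low-temperature responsiveness"),
    CisElement("Sp1", ("CC(G/A)CCC", "GGGCGG"), "Light-responsive element"),
    CisElement("TCT-motif", ("TCTTAC",), "Part of a light-responsive element"),
    CisElement("chs-CMA1a", ("TTACTTAA",), "Part of a light-responsive element"),
    CisElement("rbcS-CMA7a", ("GTCGATAAGG",),
               "Part of a light-responsive element"),
)


def load_element_table(source: str | Path | None = None) -> list[CisElement]:
    """The built-in element dictionary, or a custom TSV
    (name <TAB> sequence <TAB> function; rows with one name merge)."""
    if source is None:
        for el in DEFAULT_ELEMENTS:
            el.expanded()  # validates patterns
        return list(DEFAULT_ELEMENTS)
    rows: dict[str, dict] = {}
    order: list[str] = []
    with open(source) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise PromoterScanError(f"malformed element table row {ln}: "
                                        f"{line!r}")
            name, seq = parts[0], parts[1]
            func = parts[2] if len(parts) > 2 else ""
            _expand_pattern(seq, name)  # validate, names the row on error
            if name not in rows:
                rows[name] = {"seqs": [], "func": func}
                order.append(name)
            rows[name]["seqs"].append(seq)
    if not order:
        raise PromoterScanError("element table is empty")
    return [CisElement(n, tuple(rows[n]["seqs"]), rows[n]["func"])
            for n in order]


def write_element_table(elements: list[CisElement], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("#name\tsequence\tfunction\n")
        for el in elements:
            for seq in el.sequences:
                fh.write(f"{el.name}\t{seq}\t{el.function}\n")


@dataclass(frozen=True)
class ElementHit:
    element: str
    pattern: str          # matched literal pattern (element orientation)
    position: int         # 1-based start on the given (+) sequence
    strand: str


def scan_promoter(seq: str, elements: list[CisElement] | None = None,
                  both_strands: bool = True,
                  ) -> tuple[list[ElementHit], dict[str, int]]:
    """All element occurrences in a promoter plus per-element counts.

    Overlapping occurrences all count. A minus-strand hit at (1-based)
    position p means the reverse complement of the pattern occupies
    seq[p-1 : p-1+len]; palindromes are deduplicated by (element, position).
    Counts carry an entry (possibly 0) for every element scanned.
    """
    if not seq:
        raise PromoterScanError("empty promoter sequence")
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        raise PromoterScanError("non-DNA characters in promoter sequence")
    if elements is None:
        elements = load_element_table()
    hits: list[ElementHit] = []
    seen: set[tuple[str, int]] = set()
    for el in elements:
        for pat in el.expanded():
            for strand in ("+", "-") if both_strands else ("+",):
                probe = pat if strand == "+" else reverse_complement(pat)
                start = seq.find(probe)
                while start != -1:
                    key = (el.name, start + 1)
                    if key not in seen:
                        seen.add(key)
                        hits.append(ElementHit(el.name, pat, start + 1, strand))
                    start = seq.find(probe, start + 1)
    hits.sort(key=lambda h: (h.position, h.element, h.strand))
    counts = {el.name: 0 for el in elements}
    for h in hits:
        counts[h.element] += 1
    return hits, counts
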