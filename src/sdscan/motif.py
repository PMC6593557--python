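"""TRA/TRA-2 binding-site (dsxRE-type) element definition, scanning, and logos.

The element is a 13-bp exonic/intronic splicing-enhancer repeat. In sand
flies every occurrence carries an invariant 8-bp core, CAATCAAC; the four
bases upstream and the single base downstream vary between occurrences.
Scanning therefore keys on the core — contexts are carried along as
annotation so that matched 13-mers can feed the consensus logo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from sdscan.seq_io import SequenceRecord, SequenceError, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

SANDFLY_CORE = "CAATCAAC"


@dataclass(frozen=True)
class MotifModel:
    """Anatomy of the element: variable 5' context + invariant core + variable 3' base.

    Presets:
      * ``sandfly_core`` — exact CAATCAAC core, 4+1 context bases (13-mer element).
      * ``brachycera_13mer`` — same core with IUPAC-degenerate context allowed
        in matching (contexts become part of the pattern, core still fixed).
      * ``custom`` — caller-supplied core/contexts.
    """

    name: str = "tra_tra2_site"
    core: str = SANDFLY_CORE
    upstream_context: int = 4
    downstream_context: int = 1
    max_core_mismatches: int = 0
    preset: str = "sandfly_core"
    context_pattern_5p: str = "NNNN"  # used only by brachycera_13mer matching
    context_pattern_3p: str = "N"

    def __post_init__(self) -> None:
        if self.max_core_mismatches >= len(self.core):
            raise ValueError("max_core_mismatches must be < core length")
        if self.preset not in ("sandfly_core", "brachycera_13mer", "custom"):
            raise ValueError(f"unknown preset {self.preset!r}")

    @property
    def element_length(self) -> int:
        return self.upstream_context + len(self.core) + self.downstream_context


@dataclass(frozen=True)
class MotifHit:
    """One located element occurrence, in forward-strand coordinates.

    ``element_start/end`` extend the core by the context widths, clipped at
    the sequence ends; ``matched_element`` is the corresponding slice
    (reverse-complemented for strand '-').
    """

    seq_id: str
    core_start: int
    core_end: int
    element_start: int
    element_end: int
    strand: str
    matched_element: str
    mismatches: int


@dataclass(frozen=True)
class LogoColumn:
    """Per-position base counts/frequencies and information content (bits)."""

    position: int
    counts: dict = field(default_factory=dict)
    frequencies: dict = field(default_factory=dict)
    information_content: float = 0.0


def _core_matches(window: str, core: str, max_mm: int) -> int | None:
    """Mismatch count if window matches core within budget, else None. N never matches."""
    mm = 0
    for a, b in zip(window, core):
        if a == "N" or a != b:
            mm += 1
            if mm > max_mm:
                return None
    return mm


def _find_all(seq: str, pattern: str) -> list[int]:
    """All (overlapping) exact occurrence starts of pattern in seq."""
    out, i = [], seq.find(pattern)
    while i != -1:
        out.append(i)
        i = seq.find(pattern, i + 1)
    return out


def _context_ok(seq: str, start: int, pattern: str) -> bool:
    """Degenerate context check for the brachycera_13mer preset; clipped context passes."""
    for offset, sym in enumerate(pattern):
        pos = start + offset
        if pos < 0 or pos >= len(seq):
            continue
        base = seq[pos]
        if base == "N" or base not in IUPAC[sym]:
            return False
    return True


def scan_sequence(
    rec: SequenceRecord, model: MotifModel | None = None, strands: str = "forward"
) -> list[MotifHit]:
    """Report every element occurrence, overlapping ones included.

    Hits are sorted by core_start (strand '+' before '-' at equal start);
    minus-strand hits are reported in forward-strand coordinates.
    """
    if rec.kind != "nucleotide":
        raise SequenceError("scan_sequence requires a nucleotide record")
    if strands not in ("forward", "both"):
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    model = model or MotifModel()
    hits = list(_scan_strand(rec, model, "+"))
    if strands == "both":
        hits.extend(_scan_strand(rec, model, "-"))
    hits.sort(key=lambda h: (h.core_start, h.strand))
    return hits


def _scan_strand(rec: SequenceRecord, model: MotifModel, strand: str):
    seq = rec.residues if strand == "+" else reverse_complement(rec.residues)
    n = len(seq)
    k = len(model.core)
    up, down = model.upstream_context, model.downstream_context
    if model.max_core_mismatches == 0:
        positions = _find_all(seq, model.core)
    else:
        positions = range(n - k + 1)
    for i in positions:
        mm = _core_matches(seq[i : i + k], model.core, model.max_core_mismatches)
        if mm is None:
            continue
        if model.preset == "brachycera_13mer":
            if not _context_ok(seq, i - up, model.context_pattern_5p):
                continue
            if not _context_ok(seq, i + k, model.context_pattern_3p):
                continue
        elem_start = max(0, i - up)
        elem_end = min(n, i + k + down)
        matched = seq[elem_start:elem_end]
        if strand == "+":
            yield MotifHit(rec.id, i, i + k, elem_start, elem_end, "+", matched, mm)
        else:
            # map back to forward coordinates
            yield MotifHit(
                rec.id,
                n - (i + k),
                n - i,
                n - elem_end,
                n - elem_start,
                "-",
                matched,
                mm,
            )


def is_full_element(hit: MotifHit, model: MotifModel | None = None) -> bool:
    model = model or MotifModel()
    return (hit.element_end - hit.element_start) == model.element_length


def build_logo(hits: list[MotifHit], element_length: int = 13) -> list[LogoColumn]:
    """Column profile of full-length matched elements.

    Information content per column is 2 − H (Shannon entropy in bits) of
    the observed frequency vector; no small-sample correction, no
    pseudocounts. Clipped elements are excluded (their count is available
    to callers via :func:`is_full_element`).
    """
    usable = [h.matched_element for h in hits
              if (h.element_end - h.element_start) == element_length]
    if not usable:
        raise ValueError("no full-length elements to build a logo from")
    columns = []
    n = len(usable)
    for pos in range(element_length):
        counts = {b: 0 for b in "ACGT"}
        for elem in usable:
            base = elem[pos]
            if base in counts:
                counts[base] += 1
        total = sum(counts.values())
        freqs = {b: (c / total if total else 0.0) for b, c in counts.items()}
        entropy = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        columns.append(
            LogoColumn(
                position=pos,
                counts=counts,
                frequencies=freqs,
                information_content=2.0 - entropy,
            )
        )
    return columns


def logo_rows(columns: list[LogoColumn]) -> list[dict]:
    """Tabular (TSV-ready) form of a logo: position, A, C, G, T, IC."""
    return [
        {
            "position": col.position,
            "A": col.counts.get("A", 0),
            "C": col.counts.get("C", 0),
            "G": col.counts.get("G", 0),
            "T": col.counts.get("T", 0),
            "IC": round(col.information_content, 4),
        }
        for col in columns
    ]
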