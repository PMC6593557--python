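"""Sequence I/O and basic sequence operations shared by all stages.

FASTA parsing and the genetic code are delegated to Biopython; this
module fixes the conventions the rest of the package relies on:
records are uppercased on input, internal coordinates are 0-based
half-open on the forward strand, and writers convert to GFF3 (1-based
inclusive) or BED (0-based half-open) only at the boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

# standard nuclear code, flattened once for speed
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_MAP = dict(_STANDARD_TABLE.forward_table)
_CODON_MAP.update({stop: "*" for stop in _STANDARD_TABLE.stop_codons})
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)

NUCLEOTIDE_ALPHABET = set("ACGTN")
# 20 amino acids + ambiguity X + stop
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")


class SequenceError(ValueError):
    """Malformed sequence input (bad residues, duplicate ids, empty file)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence. ``id`` is the first whitespace-delimited header token."""

    id: str
    description: str
    residues: str
    kind: str  # "nucleotide" | "protein"

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        if self.kind not in ("nucleotide", "protein"):
            raise SequenceError(f"record {self.id!r}: unknown kind {self.kind!r}")
        alphabet = NUCLEOTIDE_ALPHABET if self.kind == "nucleotide" else PROTEIN_ALPHABET
        bad = set(self.residues) - alphabet
        if bad:
            raise SequenceError(
                f"record {self.id!r}: illegal {self.kind} characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class OpenReadingFrame:
    """An open reading frame on a transcript, forward strand.

    ``end`` includes the stop codon when one terminates the frame;
    ``protein`` never includes the stop.
    """

    seq_id: str
    frame: int
    start: int
    end: int
    protein: str
    atg_initiated: bool
    stop_terminated: bool


def make_record(id: str, residues: str, kind: str = "nucleotide", description: str = "") -> SequenceRecord:
    """Build a record from an in-memory string, normalizing case."""
    return SequenceRecord(id=id, description=description or id, residues=residues.upper(), kind=kind)


def read_fasta(path: str | Path, kind: str = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into records, in file order.

    Residues are uppercased and line wrapping removed. Duplicate ids and
    residues outside the record alphabet raise :class:`SequenceError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                id=rec.id,
                description=rec.description,
                residues=str(rec.seq).upper(),
                kind=kind,
            )
        )
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.description}\n" if rec.description.startswith(rec.id) else f">{rec.id} {rec.description}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def reverse_complement(s: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    _check_nucleotide(s)
    return str(Seq(s).reverse_complement())


def translate(s: str) -> str:
    """Translate with the standard nuclear code; stops are '*', N-codons 'X'."""
    _check_nucleotide(s)
    if len(s) % 3 != 0:
        raise SequenceError(f"length {len(s)} not divisible by 3")
    return "".join(
        "X" if "N" in (codon := s[i : i + 3]) else _CODON_MAP[codon]
        for i in range(0, len(s), 3)
    )


def _check_nucleotide(s: str) -> None:
    bad = set(s) - NUCLEOTIDE_ALPHABET
    if bad:
        raise SequenceError(f"not a nucleotide string (found {sorted(bad)})")


def find_orfs(
    rec: SequenceRecord,
    min_codons: int = 50,
    require_atg: bool = True,
    forward_only: bool = True,
) -> list[OpenReadingFrame]:
    """Find open reading frames on a transcript.

    Transcripts are assumed already oriented, so only the three forward
    frames are searched by default. ORFs are sorted by protein length
    descending, ties by start ascending. ``min_codons`` counts coding
    codons (the protein length), not the stop.
    """
    if rec.kind != "nucleotide":
        raise SequenceError(f"find_orfs requires a nucleotide record, got {rec.kind}")
    strands = [rec.residues] if forward_only else [rec.residues, reverse_complement(rec.residues)]
    orfs: list[OpenReadingFrame] = []
    for strand_seq in strands:
        orfs.extend(_scan_frames(rec.id, strand_seq, min_codons, require_atg))
    orfs.sort(key=lambda o: (-len(o.protein), o.start))
    return orfs


def _scan_frames(seq_id: str, s: str, min_codons: int, require_atg: bool) -> list[OpenReadingFrame]:
    orfs = []
    n = len(s)
    for frame in range(3):
        pos = frame
        open_start: int | None = None
        while pos + 3 <= n:
            codon = s[pos : pos + 3]
            if open_start is None:
                if (codon == "ATG" if require_atg else codon not in STOP_CODONS):
                    open_start = pos
            if open_start is not None and codon in STOP_CODONS:
                orf = _make_orf(seq_id, s, frame, open_start, pos + 3, stop=True)
                if len(orf.protein) >= min_codons:
                    orfs.append(orf)
                open_start = None
            pos += 3
        if open_start is not None:
            end = open_start + ((n - open_start) // 3) * 3
            orf = _make_orf(seq_id, s, frame, open_start, end, stop=False)
            if len(orf.protein) >= min_codons:
                orfs.append(orf)
    return orfs


def _make_orf(seq_id: str, s: str, frame: int, start: int, end: int, stop: bool) -> OpenReadingFrame:
    coding = s[start : end - 3] if stop else s[start:end]
    protein = translate(coding)
    return OpenReadingFrame(
        seq_id=seq_id,
        frame=frame,
        start=start,
        end=end,
        protein=protein,
        atg_initiated=s[start : start + 3] == "ATG",
        stop_terminated=stop,
    )


@dataclass(frozen=True)
class Feature:
    """A located feature for the GFF3/BED writers (0-based half-open)."""

    seq_id: str
    start: int
    end: int
    type: str = "region"
    strand: str = "+"
    name: str = "."
    score: float | None = None
    attributes: dict = field(default_factory=dict)


def _check_bounds(feat: Feature, seq_lengths: dict[str, int] | None) -> None:
    if feat.start < 0 or feat.end <= feat.start:
        raise ValueError(f"feature {feat.name}: bad interval [{feat.start},{feat.end})")
    if seq_lengths is not None and feat.seq_id in seq_lengths and feat.end > seq_lengths[feat.seq_id]:
        raise ValueError(
            f"feature {feat.name}: end {feat.end} beyond {feat.seq_id} length {seq_lengths[feat.seq_id]}"
        )


def write_gff3(features: Sequence[Feature], path: str | Path, source: str = "sdscan",
               seq_lengths: dict[str, int] | None = None) -> None:
    """Write features as GFF3; internal half-open coordinates become 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            _check_bounds(feat, seq_lengths)
            attrs = dict(feat.attributes)
            if feat.name != ".":
                attrs.setdefault("ID", feat.name)
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            score = "." if feat.score is None else f"{feat.score:g}"
            fh.write(
                "\t".join(
                    [feat.seq_id, source, feat.type, str(feat.start + 1), str(feat.end),
                     score, feat.strand, ".", attr_str]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[Feature]:
    """Read back a GFF3 written by :func:`write_gff3` (coordinate round-trip)."""
    feats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            attrs = {}
            if cols[8] != ".":
                for kv in cols[8].split(";"):
                    k, _, v = kv.partition("=")
                    attrs[k] = v
            feats.append(
                Feature(
                    seq_id=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    type=cols[2],
                    strand=cols[6],
                    name=attrs.get("ID", "."),
                    score=None if cols[5] == "." else float(cols[5]),
                    attributes=attrs,
                )
            )
    return feats


def write_bed(features: Sequence[Feature], path: str | Path,
              seq_lengths: dict[str, int] | None = None) -> None:
    """Write features as BED6 (already 0-based half-open internally)."""
    with open(path, "w") as fh:
        for feat in features:
            _check_bounds(feat, seq_lengths)
            score = 0 if feat.score is None else feat.score
            fh.write(
                f"{feat.seq_id}\t{feat.start}\t{feat.end}\t{feat.name}\t{score:g}\t{feat.strand}\n"
            )


def write_tsv(rows: Sequence[dict], path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write dict rows as a TSV report with a header row."""
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(columns), delimiter="\t")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
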