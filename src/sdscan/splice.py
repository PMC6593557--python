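"""Spliced cDNA-to-locus alignment, gene models, splice-site scoring, AS events.

The aligner is built for the setting it is used in: cDNA clones aligned
back to a kb-scale genomic amplicon from the same individuals, so exon
blocks match the locus exactly (no substitutions inside blocks). It
anchors maximal exact k-mer matches, chains the highest-coverage
collinear subset by dynamic programming (ties broken toward fewer
introns), and then slides each junction within its sequence-ambiguity
interval to satisfy the GT-AG rule, preferring the left-most compliant
placement. Terminal cDNA bases that cannot be placed (e.g. UTR overhangs
beyond the amplicon) are reported as clipped, never forced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from sdscan.seq_io import SequenceRecord, SequenceError


class AlignmentFailure(Exception):
    """No collinear chain covers enough of the cDNA."""


class SpliceJunctionError(Exception):
    """GT-AG could not be satisfied at a junction under enforcement."""

    def __init__(self, msg: str, cdna_pos: int, donor: int, acceptor: int):
        super().__init__(msg)
        self.cdna_pos = cdna_pos
        self.donor = donor
        self.acceptor = acceptor


@dataclass(frozen=True)
class TranscriptAlignment:
    """Exon blocks of one cDNA on a locus, all 0-based half-open, forward strand.

    ``blocks``: (cdna_start, cdna_end, locus_start, locus_end), equal lengths.
    ``introns``: (locus_start, locus_end, donor_dinuc, acceptor_dinuc).
    """

    cdna_id: str
    locus_id: str
    blocks: tuple
    introns: tuple
    clipped_5p: int
    clipped_3p: int

    @property
    def aligned_bases(self) -> int:
        return sum(b[1] - b[0] for b in self.blocks)


@dataclass(frozen=True)
class GeneModel:
    """Exon-intron structure of a locus, merged over isoform alignments.

    ``introns`` is the reference intron set (from the most-spliced
    isoform); ``alt_introns`` records every other distinct intron seen
    (alternative donors/acceptors).
    """

    locus_id: str
    strand: str
    exons: tuple
    introns: tuple
    alt_introns: tuple
    source_isoforms: tuple


@dataclass(frozen=True)
class SpliceSiteScore:
    site_type: str  # "donor" | "acceptor"
    locus_position: int
    window: str
    score: float
    klass: str  # "strong" | "weak"


@dataclass(frozen=True)
class ASEvent:
    """A classified splicing difference between two isoforms of one locus."""

    event_type: str  # alt_donor_5p | alt_acceptor_3p | intron_retention | cassette_exon | unspliced
    start: int
    end: int
    isoform_pair: tuple


# ---------------------------------------------------------------- alignment


def _maximal_anchors(cdna: str, locus: str, k: int) -> list[tuple[int, int, int]]:
    """Maximal exact matches ≥ k as (cdna_start, locus_start, length)."""
    index: dict[str, list[int]] = {}
    for j in range(len(locus) - k + 1):
        index.setdefault(locus[j : j + k], []).append(j)
    anchors = []
    seen: set[tuple[int, int]] = set()  # (diagonal, cdna_start) of emitted maximal matches
    for i in range(len(cdna) - k + 1):
        for j in index.get(cdna[i : i + k], ()):
            if i > 0 and j > 0 and cdna[i - 1] == locus[j - 1]:
                continue  # not left-maximal; covered by an earlier seed
            key = (j - i, i)
            if key in seen:
                continue
            seen.add(key)
            length = k
            while i + length < len(cdna) and j + length < len(locus) and cdna[i + length] == locus[j + length]:
                length += 1
            anchors.append((i, j, length))
    return anchors


def _chain(anchors, min_intron: int):
    """Highest-coverage collinear chain; returns list of trimmed blocks.

    Chains require cDNA contiguity after trimming anchor overlaps (exact
    alignment model) and locus gaps of at least ``min_intron`` between
    consecutive blocks.
    """
    if not anchors:
        return []
    anchors = sorted(anchors, key=lambda a: (a[0], a[1]))
    n = len(anchors)
    score = [a[2] for a in anchors]
    nintr = [0] * n
    prev = [-1] * n
    trim = [0] * n
    for b in range(n):
        ib, jb, Lb = anchors[b]
        for a in range(b):
            ia, ja, La = anchors[a]
            o = (ia + La) - ib  # cDNA overlap to trim off the front of b
            if o < 0:
                continue  # internal cDNA gap: not allowed in the exact model
            if Lb - o < 1:
                continue
            jb_eff = jb + o
            intron_len = jb_eff - (ja + La)
            if intron_len < min_intron:
                continue
            cand = score[a] + (Lb - o)
            cand_intr = nintr[a] + 1
            if cand > score[b] or (cand == score[b] and cand_intr < nintr[b]):
                score[b] = cand
                nintr[b] = cand_intr
                prev[b] = a
                trim[b] = o
    best = max(range(n), key=lambda b: (score[b], -nintr[b]))
    chain = []
    b = best
    while b != -1:
        ib, jb, Lb = anchors[b]
        o = trim[b]
        chain.append((ib + o, ib + Lb, jb + o, jb + Lb))
        b = prev[b]
    chain.reverse()
    return chain


def _ambiguity_range(locus: str, donor: int, acceptor: int, left_max: int, right_max: int):
    """Shifts s for which moving the junction by s leaves the spliced sequence unchanged."""
    shifts = [0]
    s = 0
    while -s < left_max:
        s -= 1
        if donor + s < 0 or acceptor + s < 1:
            break
        if locus[donor + s] != locus[acceptor + s]:
            break
        shifts.append(s)
    s = 0
    while s < right_max:
        if donor + s >= len(locus) or acceptor + s >= len(locus):
            break
        if locus[donor + s] != locus[acceptor + s]:
            break
        s += 1
        shifts.append(s)
    return sorted(shifts)


def spliced_align(
    cdna: SequenceRecord,
    locus: SequenceRecord,
    k: int = 15,
    min_intron: int = 30,
    enforce_gt_ag: bool = True,
) -> TranscriptAlignment:
    """Align a cDNA to its genomic locus, recovering exon blocks and introns.

    Raises :class:`AlignmentFailure` when no chain covers ≥ 50% of the
    cDNA and :class:`SpliceJunctionError` when a junction cannot be
    placed on GT-AG under enforcement (callers may retry with
    ``enforce_gt_ag=False``).
    """
    if cdna.kind != "nucleotide" or locus.kind != "nucleotide":
        raise SequenceError("spliced_align requires nucleotide records")
    c, g = cdna.residues, locus.residues
    anchors = _maximal_anchors(c, g, k)
    blocks = _chain(anchors, min_intron)
    aligned = sum(b[1] - b[0] for b in blocks)
    if aligned < 0.5 * len(c):
        raise AlignmentFailure(
            f"{cdna.id} vs {locus.id}: best chain covers {aligned}/{len(c)} bases (<50%)"
        )

    blocks, introns = _place_junctions(c, g, blocks, enforce_gt_ag)
    return TranscriptAlignment(
        cdna_id=cdna.id,
        locus_id=locus.id,
        blocks=tuple(blocks),
        introns=tuple(introns),
        clipped_5p=blocks[0][0],
        clipped_3p=len(c) - blocks[-1][1],
    )


def _place_junctions(c: str, g: str, blocks, enforce_gt_ag: bool):
    """Slide each junction within its ambiguity interval onto GT..AG (left-most)."""
    blocks = [list(b) for b in blocks]
    introns = []
    for idx in range(len(blocks) - 1):
        p, q = blocks[idx], blocks[idx + 1]
        donor, acceptor = p[3], q[2]  # intron = g[donor:acceptor]
        left_max = p[3] - p[2] - 1  # keep ≥1 base in each flanking block
        right_max = q[3] - q[2] - 1
        chosen = 0
        if enforce_gt_ag:
            candidates = [
                s
                for s in _ambiguity_range(g, donor, acceptor, left_max, right_max)
                if g[donor + s : donor + s + 2] == "GT"
                and g[acceptor + s - 2 : acceptor + s] == "AG"
            ]
            if not candidates:
                raise SpliceJunctionError(
                    f"no GT-AG placement for intron g[{donor}:{acceptor}]",
                    cdna_pos=p[1],
                    donor=donor,
                    acceptor=acceptor,
                )
            chosen = candidates[0]
        if chosen:
            p[1] += chosen
            p[3] += chosen
            q[0] += chosen
            q[2] += chosen
        d, a = p[3], q[2]
        introns.append((d, a, g[d : d + 2], g[a - 2 : a]))
    return [tuple(b) for b in blocks], introns


# ---------------------------------------------------------------- gene model


def build_gene_model(alignments: Sequence[TranscriptAlignment]) -> GeneModel:
    """Merge isoform alignments on one locus into an exon-intron model.

    The exon set is the union of all blocks projected onto the locus,
    split at every distinct junction; the reference introns come from the
    most-spliced isoform, remaining distinct introns are recorded as
    alternatives.
    """
    if not alignments:
        raise ValueError("no alignments supplied")
    loci = {a.locus_id for a in alignments}
    if len(loci) > 1:
        raise ValueError(f"alignments on different loci: {sorted(loci)}")

    intervals = sorted((b[2], b[3]) for a in alignments for b in a.blocks)
    boundaries = sorted({x for iv in intervals for x in iv})
    # union of coverage
    merged = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    exons = []
    for s, e in merged:
        cuts = [s] + [b for b in boundaries if s < b < e] + [e]
        exons.extend((cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1))

    reference = max(alignments, key=lambda a: len(a.introns))
    ref_introns = tuple(reference.introns)
    ref_set = {(i[0], i[1]) for i in ref_introns}
    alt = []
    seen = set()
    for a in alignments:
        for i in a.introns:
            key = (i[0], i[1])
            if key not in ref_set and key not in seen:
                seen.add(key)
                alt.append(i)
    return GeneModel(
        locus_id=alignments[0].locus_id,
        strand="+",
        exons=tuple(exons),
        introns=ref_introns,
        alt_introns=tuple(sorted(alt)),
        source_isoforms=tuple(a.cdna_id for a in alignments),
    )


def splice_by_model(locus: str, alignment: TranscriptAlignment) -> str:
    """The locus sequence spliced according to an alignment's blocks."""
    return "".join(locus[b[2] : b[3]] for b in alignment.blocks)


# ---------------------------------------------------------------- site scoring

# Per-position agreement weights, consensus base(s) = 1.0. Donor consensus
# MAG|GTRAGT, acceptor = polypyrimidine tract + NCAG|G; GT / AG positions
# are mandatory (whole score 0 when absent). Weights are a fixed canonical
# metazoan consensus table, not species-trained.
_DONOR_WEIGHTS = [
    {"A": 1.0, "C": 1.0, "G": 0.2, "T": 0.2},    # -3 (M)
    {"A": 1.0, "C": 0.3, "G": 0.4, "T": 0.2},    # -2
    {"G": 1.0, "A": 0.3, "C": 0.2, "T": 0.2},    # -1
    "G!",                                          # +1 mandatory
    "T!",                                          # +2 mandatory
    {"A": 1.0, "G": 1.0, "C": 0.1, "T": 0.15},   # +3 (R)
    {"A": 1.0, "C": 0.3, "G": 0.35, "T": 0.25},  # +4
    {"G": 1.0, "A": 0.3, "C": 0.15, "T": 0.2},   # +5
    {"T": 1.0, "A": 0.3, "C": 0.25, "G": 0.25},  # +6
]
_PY = {"C": 1.0, "T": 1.0, "A": 0.2, "G": 0.2}
_ACCEPTOR_WEIGHTS = (
    [_PY] * 10                                    # -14..-5 polypyrimidine
    + [{"A": 1.0, "C": 1.0, "G": 1.0, "T": 1.0}]  # -4 (N)
    + [{"C": 1.0, "T": 0.5, "A": 0.3, "G": 0.2}]  # -3
    + ["A!", "G!"]                                 # -2,-1 mandatory AG
    + [{"G": 1.0, "A": 0.5, "C": 0.3, "T": 0.3}]  # +1 exonic
)

STRONG_THRESHOLD = 0.7


def score_splice_site(
    locus: SequenceRecord,
    position: int,
    site_type: str,
    strong_threshold: float = STRONG_THRESHOLD,
) -> SpliceSiteScore:
    """Score a donor (position = intron start) or acceptor (position = intron
    end, exclusive) against the built-in consensus weights.

    Donor window: exonic −3..−1 + intronic +1..+6; acceptor window:
    intronic −14..−1 + first exonic base. Score is the mean per-position
    weight in [0,1], forced to 0 when the mandatory GT/AG is absent.
    """
    g = locus.residues
    if site_type == "donor":
        start, end = position - 3, position + 6
        weights = _DONOR_WEIGHTS
    elif site_type == "acceptor":
        start, end = position - 14, position + 1
        weights = _ACCEPTOR_WEIGHTS
    else:
        raise ValueError(f"site_type must be donor/acceptor, got {site_type!r}")
    if start < 0 or end > len(g):
        raise ValueError(f"{site_type} window [{start},{end}) outside locus bounds")
    window = g[start:end]
    total = 0.0
    for base, w in zip(window, weights):
        if isinstance(w, str):  # mandatory position, e.g. "G!"
            if base != w[0]:
                total = 0.0
                break
            total += 1.0
        else:
            total += w.get(base, 0.0)
    else:
        pass
    score = total / len(weights) if total > 0 else 0.0
    return SpliceSiteScore(
        site_type=site_type,
        locus_position=position,
        window=window,
        score=score,
        klass="strong" if score >= strong_threshold else "weak",
    )


# ---------------------------------------------------------------- AS events


def _exonic_cover(alignment: TranscriptAlignment, start: int, end: int) -> bool:
    """True when [start, end) on the locus is fully inside the alignment's blocks."""
    pos = start
    for _, _, ls, le in alignment.blocks:
        if ls <= pos < le:
            pos = min(end, le)
            if pos >= end:
                return True
    return pos >= end


def classify_events(
    reference: TranscriptAlignment, alternative: TranscriptAlignment
) -> list[ASEvent]:
    """Classify the splicing differences of ``alternative`` against ``reference``.

    Event taxonomy: intron_retention (reference intron fully exonic in the
    alternative), alt_donor_5p / alt_acceptor_3p (one shared boundary),
    cassette_exon (reference exon skipped between two reference introns
    fused into one alternative intron), unspliced (alternative has no
    introns at all while the reference has at least one).
    """
    if reference.locus_id != alternative.locus_id:
        raise ValueError("alignments are on different loci")
    pair = (reference.cdna_id, alternative.cdna_id)
    ref_introns = [(i[0], i[1]) for i in reference.introns]
    alt_introns = [(i[0], i[1]) for i in alternative.introns]

    if not ref_introns:
        return []
    if not alt_introns:
        return [ASEvent("unspliced", ref_introns[0][0], ref_introns[-1][1], pair)]

    events: list[ASEvent] = []
    consumed: set[tuple[int, int]] = set()

    # cassette exons: one alternative intron fusing ≥2 reference introns
    for a_s, a_e in alt_introns:
        inside = [iv for iv in ref_introns if iv[0] >= a_s and iv[1] <= a_e]
        if len(inside) >= 2 and inside[0][0] == a_s and inside[-1][1] == a_e:
            for i in range(len(inside) - 1):
                events.append(ASEvent("cassette_exon", inside[i][1], inside[i + 1][0], pair))
            consumed.update(inside)

    alt_set = set(alt_introns)
    for rs, re in ref_introns:
        if (rs, re) in consumed or (rs, re) in alt_set:
            continue
        same_acceptor = [iv for iv in alt_introns if iv[1] == re and iv[0] != rs]
        same_donor = [iv for iv in alt_introns if iv[0] == rs and iv[1] != re]
        if same_acceptor:
            a_s = same_acceptor[0][0]
            events.append(ASEvent("alt_donor_5p", min(rs, a_s), max(rs, a_s), pair))
        elif same_donor:
            a_e = same_donor[0][1]
            events.append(ASEvent("alt_acceptor_3p", min(re, a_e), max(re, a_e), pair))
        elif _exonic_cover(alternative, rs, re):
            events.append(ASEvent("intron_retention", rs, re, pair))
    events.sort(key=lambda e: (e.start, e.end))
    return events
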