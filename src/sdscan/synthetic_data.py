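"""Seeded generators for every input the analysis consumes, with ground truth.

Three generators:

* :func:`generate_transcriptome` — a background of motif-core-free
  transcripts (log-normal lengths, configurable GC) plus one planted
  tra-like transcript: an SR-rich coding region interrupted by a
  retained intron that carries a cluster of 13-bp elements.
* :func:`generate_locus_with_isoforms` — a four-exon/three-intron locus
  (all introns GT..AG, the second carrying the element cluster and the
  alternative splice sites) together with the five isoform cDNAs:
  F1 fully spliced, F2 alternative 3' acceptor, F3 intron retention,
  M1 alternative 5' donor, M2 unspliced.
* :func:`generate_codon_pair` — a codon-sequence pair diverged at a
  controlled dN/dS by proposal-acceptance simulation.

Every generator validates its own ground truth by running the
corresponding analysis stage before returning, and is byte-deterministic
given the seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace

from sdscan import domains as domains_mod
from sdscan.motif import MotifModel, SANDFLY_CORE, scan_sequence
from sdscan.seq_io import (
    STOP_CODONS,
    SequenceRecord,
    find_orfs,
    make_record,
    reverse_complement,
    translate,
)
from sdscan.splice import GeneModel, classify_events, spliced_align

BASES_STR = "ACGT"

# codon pools controlling SR-rich exon composition
R_CODONS = ("AGA", "AGG", "CGT", "CGC", "CGA", "CGG")
S_CODONS = ("AGC", "AGT", "TCT", "TCC", "TCA", "TCG")
# neutral pool chosen to avoid R, S, stops and M (keeps ATG starts unique-ish)
NEUTRAL_CODONS = ("GCT", "GCC", "GAA", "GAT", "CTG", "ATT", "GGT", "TTC", "ACA", "GTT")

ISOFORM_NAMES = ("F1", "F2", "F3", "M1", "M2")


@dataclass(frozen=True)
class PlantedLocusSpec:
    """Structure of the planted tra-like locus.

    Defaults emulate the observed geometry: six 13-bp elements whose
    core starts are spaced 55–70 bp apart (expected cluster span
    5 × 62.5 + 8 ≈ 320 bp) inside the sex-specifically spliced intron 2,
    flanked by exons in which half of the codons encode R or S.
    """

    n_elements: int = 6
    element_gap_range: tuple = (55, 70)
    intron_lengths: tuple = (60, 500, 60)
    exon_cds_codons: tuple = (30, 30, 60, 60)
    utr_length: int = 30
    exon_sr_fraction: float = 0.5
    alt_donor_offset: int = 232      # M1 donor, bp downstream of the exon-2 junction
    alt_acceptor_tail: int = 100     # bp of intron 2 retained by F2
    isoform_set: tuple = ISOFORM_NAMES


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_background: int = 500
    length_median: int = 1500        # log-normal median of background lengths
    length_sigma: float = 0.35
    gc_content: float = 0.40
    planted: PlantedLocusSpec | None = field(default_factory=PlantedLocusSpec)

    def __post_init__(self) -> None:
        if self.n_background <= 0 or self.length_median <= 0:
            raise ValueError("counts and lengths must be positive")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0,1)")


@dataclass(frozen=True)
class GroundTruth:
    planted_seq_id: str | None = None
    element_core_starts: tuple = ()
    true_gene_model: GeneModel | None = None
    true_junctions: dict = field(default_factory=dict)   # isoform -> ((start,end),...)
    true_events: dict = field(default_factory=dict)      # isoform -> event label
    true_omega: float | None = None
    realized_divergence: float | None = None


# ----------------------------------------------------------------- sequences


def _random_seq(rng: random.Random, length: int, gc: float = 0.40) -> str:
    # integer pool keeps base composition exact for the default GC
    ng = max(1, round(gc * 10 / 2))
    pool = "G" * ng + "C" * ng + "A" * (5 - ng) + "T" * (5 - ng)
    return "".join(pool[rng.randrange(10)] for _ in range(length))


def _core_free_seq(rng: random.Random, length: int, gc: float, core: str) -> str:
    rc = reverse_complement(core)
    for _ in range(1000):
        s = _random_seq(rng, length, gc)
        if core not in s and rc not in s:
            return s
    raise RuntimeError("could not generate a core-free sequence")


def _sr_exon_cds(rng: random.Random, n_codons: int, sr_fraction: float, core: str) -> str:
    """CDS for one exon: ``sr_fraction`` of codons from the R/S pools, rest neutral."""
    n_sr = round(sr_fraction * n_codons)
    for _ in range(1000):
        flags = [True] * n_sr + [False] * (n_codons - n_sr)
        rng.shuffle(flags)
        codons = []
        for is_sr in flags:
            if is_sr:
                pool = R_CODONS if rng.randrange(2) else S_CODONS
                codons.append(pool[rng.randrange(len(pool))])
            else:
                codons.append(NEUTRAL_CODONS[rng.randrange(len(NEUTRAL_CODONS))])
        s = "".join(codons)
        if core not in s and reverse_complement(core) not in s:
            return s
    raise RuntimeError("could not generate a core-free SR exon")


# ------------------------------------------------------------- locus builder


def _build_intron2(
    rng: random.Random, spec: PlantedLocusSpec, core: str
) -> tuple[str, list[int], int, int]:
    """Intron 2 with the element cluster, alt donor GT and alt acceptor AG.

    Returns (sequence, core offsets, alt_donor offset, alt_acceptor offset),
    all offsets relative to the intron start.
    """
    length = spec.intron_lengths[1]
    lo, hi = spec.element_gap_range
    first = 24  # room for GT + an early in-frame stop
    alt_acc = length - spec.alt_acceptor_tail
    alt_acc -= alt_acc % 3  # retained tail starts in frame

    for _ in range(200):
        gaps = [lo + rng.randrange(hi - lo + 1) for _ in range(spec.n_elements - 1)]
        starts = [first]
        for gp in gaps:
            starts.append(starts[-1] + gp)
        if starts[-1] + len(core) + 1 > alt_acc - 5:
            continue  # cluster must not run into the retained tail
        reserved = [(s - 4, s + len(core) + 1) for s in starts]  # full 13-mer elements
        # alt donor GT inside a gap, at/after the nominal offset
        alt_don = None
        for pos in range(min(spec.alt_donor_offset, length - 40), alt_acc - 10):
            if all(pos + 2 <= a or pos >= b for a, b in reserved) and pos > 8:
                alt_don = pos
                break
        if alt_don is None:
            continue

        seq = list(_core_free_seq(rng, length, 0.40, core))
        seq[0:2] = "GT"
        seq[-2:] = "AG"
        seq[6:9] = "TAA"                      # in-frame stop for M1/M2/F3 products
        for s in starts:
            seq[s : s + len(core)] = core
        seq[alt_don : alt_don + 2] = "GT"
        seq[alt_acc - 2 : alt_acc] = "AG"     # F2 acceptor
        seq[alt_acc : alt_acc + 3] = "TAA"    # in-frame stop for the F2 product
        s = "".join(seq)
        # planting must not create extra cores, and core count must be exact
        if s.count(core) == spec.n_elements and reverse_complement(core) not in s:
            return s, starts, alt_don, alt_acc
    raise ValueError("element cluster does not fit in intron 2 for this spec")


def _plain_intron(rng: random.Random, length: int, core: str) -> str:
    if length < 30:
        raise ValueError(f"intron length {length} below the 30 bp minimum")
    seq = list(_core_free_seq(rng, length, 0.40, core))
    seq[0:2] = "GT"
    seq[-2:] = "AG"
    seq[6:9] = "TAA"  # in-frame stop once retained
    return "".join(seq)


def _fix_junction_bases(exons: list[str], introns: list[str]) -> None:
    """Remove junction ambiguity so true splice sites are uniquely recoverable.

    A junction can slide by ±1 only when the exon base adjacent to the
    intron equals the intron base at the other end; forcing the exon's
    last base away from 'G' and each acceptor-exon's first base away
    from 'G' kills every such shift (introns start G and end G).
    """
    for i in range(len(introns)):
        left = exons[i]
        if left[-1] == "G":
            exons[i] = left[:-1] + "A"
        right = exons[i + 1]
        if right[0] == "G":
            exons[i + 1] = "A" + right[1:]


class _RetryableArtifact(RuntimeError):
    """A chance artifact (e.g. a junction-crossing core) worth a re-draw."""


def generate_locus_with_isoforms(
    spec: PlantedLocusSpec | None = None, seed: int = 0
) -> tuple[SequenceRecord, list[SequenceRecord], GroundTruth]:
    """Generate a locus and its five sex-specific isoform cDNAs with ground truth.

    Assembly can, with small probability, create an extra core spanning
    a junction; such draws are rejected and retried deterministically so
    the emitted ground truth is always exact.
    """
    spec = spec or PlantedLocusSpec()
    if spec.n_elements < 1:
        raise ValueError("n_elements must be positive")
    if len(spec.intron_lengths) != 3 or len(spec.exon_cds_codons) != 4:
        raise ValueError("spec requires 4 exons and 3 introns")
    for attempt in range(20):
        sub_seed = (seed + attempt * 1000003) % (2**31)
        try:
            return _generate_locus_once(spec, seed, sub_seed)
        except _RetryableArtifact:
            continue
    raise RuntimeError("locus generation kept producing chance artifacts")


def _generate_locus_once(
    spec: PlantedLocusSpec, seed: int, sub_seed: int
) -> tuple[SequenceRecord, list[SequenceRecord], GroundTruth]:
    rng = random.Random(sub_seed)
    core = SANDFLY_CORE

    cds = [
        _sr_exon_cds(rng, n, spec.exon_sr_fraction, core)
        for n in spec.exon_cds_codons
    ]
    utr5 = _core_free_seq(rng, spec.utr_length, 0.40, core)
    utr3 = _core_free_seq(rng, spec.utr_length, 0.40, core)
    exons = [
        utr5 + "ATG" + cds[0],
        cds[1],
        cds[2],
        cds[3] + "TAA" + utr3,
    ]
    intron2, core_offsets, alt_don, alt_acc = _build_intron2(rng, spec, core)
    introns = [
        _plain_intron(rng, spec.intron_lengths[0], core),
        intron2,
        _plain_intron(rng, spec.intron_lengths[2], core),
    ]
    _fix_junction_bases(exons, introns)
    # guard: the UTR edit must not have broken the ATG
    assert "ATG" in exons[0]

    # locus assembly and coordinates
    parts, exon_coords, intron_coords = [], [], []
    pos = 0
    for i in range(4):
        parts.append(exons[i])
        exon_coords.append((pos, pos + len(exons[i])))
        pos += len(exons[i])
        if i < 3:
            parts.append(introns[i])
            intron_coords.append((pos, pos + len(introns[i])))
            pos += len(introns[i])
    locus_seq = "".join(parts)
    locus = make_record(f"locus_seed{seed}", locus_seq)

    i2s, i2e = intron_coords[1]
    junctions = {
        "F1": tuple(intron_coords),
        "F2": (intron_coords[0], (i2s, i2s + alt_acc), intron_coords[2]),
        "F3": (intron_coords[0], intron_coords[2]),
        "M1": (intron_coords[0], (i2s + alt_don, i2e), intron_coords[2]),
        "M2": (),
    }
    isoforms = []
    for name in spec.isoform_set:
        if name not in junctions:
            raise ValueError(f"unknown isoform {name!r}")
        cdna = _splice_out(locus_seq, junctions[name])
        isoforms.append(make_record(f"{name}_seed{seed}", cdna))

    truth = GroundTruth(
        planted_seq_id=locus.id,
        element_core_starts=tuple(i2s + off for off in core_offsets),
        true_junctions={n: junctions[n] for n in spec.isoform_set},
        true_events={
            "F1": None,
            "F2": "alt_acceptor_3p",
            "F3": "intron_retention",
            "M1": "alt_donor_5p",
            "M2": "unspliced",
        },
    )
    _self_check_locus(locus, isoforms, truth, spec)
    return locus, isoforms, truth


def _splice_out(locus: str, introns: tuple) -> str:
    out, pos = [], 0
    for s, e in introns:
        out.append(locus[pos:s])
        pos = e
    out.append(locus[pos:])
    return "".join(out)


def _self_check_locus(locus, isoforms, truth: GroundTruth, spec: PlantedLocusSpec) -> None:
    hits = scan_sequence(locus, MotifModel(), strands="forward")
    if tuple(h.core_start for h in hits) != truth.element_core_starts:
        raise _RetryableArtifact("chance extra core on the assembled locus")
    core_len = len(SANDFLY_CORE)
    for rec in isoforms:
        name = rec.id.split("_")[0]
        removed = truth.true_junctions[name]
        expected = sum(
            1
            for cs in truth.element_core_starts
            if all(cs + core_len <= s or cs >= e for s, e in removed)
        )
        if rec.residues.count(SANDFLY_CORE) != expected:
            raise _RetryableArtifact("chance core across a spliced junction")
    by_name = {r.id.split("_")[0]: r for r in isoforms}
    aligned = {}
    for name, rec in by_name.items():
        aln = spliced_align(rec, locus)
        found = tuple((i[0], i[1]) for i in aln.introns)
        if found != truth.true_junctions[name]:
            raise RuntimeError(f"generator self-check failed: junctions of {name}")
        aligned[name] = aln
    if "F1" in aligned:
        for name, aln in aligned.items():
            if name == "F1":
                continue
            events = classify_events(aligned["F1"], aln)
            labels = {e.event_type for e in events}
            if labels != {truth.true_events[name]}:
                raise RuntimeError(f"generator self-check failed: events of {name}")
        # the fully spliced isoform must encode an SR protein with an RS domain
        orfs = find_orfs(by_name["F1"], min_codons=50)
        if not orfs or not domains_mod.find_rs_domains(orfs[0].protein):
            raise RuntimeError("generator self-check failed: F1 SR ORF")


def generate_generic_locus(
    n_introns: int,
    seed: int = 0,
    intron_length_range: tuple = (30, 500),
    exon_length_range: tuple = (40, 200),
) -> tuple[SequenceRecord, SequenceRecord, tuple]:
    """A plain multi-exon locus and its fully spliced cDNA, for aligner tests.

    Returns (locus, cdna, true_introns). Introns are GT..AG; junction
    edges are built ambiguity-free (the exon base flanking each intron
    never equals the intron base at the opposite end), so the true
    junctions are the unique GT-AG placement.
    """
    if n_introns < 1:
        raise ValueError("need at least one intron")
    rng = random.Random(seed)
    core = SANDFLY_CORE
    exons = [
        _core_free_seq(
            rng,
            exon_length_range[0]
            + rng.randrange(exon_length_range[1] - exon_length_range[0] + 1),
            0.40,
            core,
        )
        for _ in range(n_introns + 1)
    ]
    introns = []
    for _ in range(n_introns):
        length = intron_length_range[0] + rng.randrange(
            intron_length_range[1] - intron_length_range[0] + 1
        )
        seq = list(_core_free_seq(rng, length, 0.40, core))
        seq[0:2] = "GT"
        seq[-2:] = "AG"
        introns.append("".join(seq))
    _fix_junction_bases(exons, introns)
    parts, true_introns = [], []
    pos = 0
    for i, ex in enumerate(exons):
        parts.append(ex)
        pos += len(ex)
        if i < n_introns:
            parts.append(introns[i])
            true_introns.append((pos, pos + len(introns[i])))
            pos += len(introns[i])
    locus = make_record(f"glocus_seed{seed}", "".join(parts))
    cdna = make_record(f"gcdna_seed{seed}", "".join(exons))
    return locus, cdna, tuple(true_introns)


# -------------------------------------------------------- transcriptome


def generate_transcriptome(
    cfg: SyntheticConfig | None = None,
) -> tuple[list[SequenceRecord], GroundTruth]:
    """Background transcripts (core-free by rejection) plus one planted
    tra-like transcript with its retained-intron element cluster."""
    cfg = cfg or SyntheticConfig()
    rng = random.Random(cfg.seed)
    core = SANDFLY_CORE
    records = []
    for i in range(cfg.n_background):
        length = max(200, round(rng.lognormvariate(
            math.log(cfg.length_median), cfg.length_sigma)))
        records.append(
            make_record(f"bg{i:05d}_seed{cfg.seed}",
                        _core_free_seq(rng, length, cfg.gc_content, core))
        )
    truth = GroundTruth()
    if cfg.planted is not None:
        locus, isoforms, locus_truth = generate_locus_with_isoforms(
            replace(cfg.planted, isoform_set=("F3",)), seed=rng.randrange(2**31)
        )
        planted = make_record(f"planted_seed{cfg.seed}", isoforms[0].residues)
        insert_at = rng.randrange(len(records) + 1)
        records.insert(insert_at, planted)
        hits = scan_sequence(planted, MotifModel())
        truth = GroundTruth(
            planted_seq_id=planted.id,
            element_core_starts=tuple(h.core_start for h in hits),
        )
        if len(hits) != cfg.planted.n_elements:
            raise RuntimeError("generator self-check failed: planted element count")
        for rec in records:
            if rec.id != planted.id and core in rec.residues:
                raise RuntimeError("generator self-check failed: background not core-free")
    return records, truth


# -------------------------------------------------------- codon pair


def generate_codon_pair(
    omega_true: float, n_codons: int, divergence: float, seed: int = 0
) -> tuple[tuple[str, str], GroundTruth]:
    """A codon-sequence pair evolved at a controlled dN/dS.

    Substitutions are proposed uniformly over positions and bases;
    synonymous proposals are accepted with probability min(1, 1/ω),
    nonsynonymous with min(1, ω); stop-creating proposals are rejected.
    The walk stops when round(divergence × 3 × n_codons) substitutions
    (summed over the two lineages) have been applied.
    """
    if omega_true < 0 or n_codons <= 0 or not 0.0 <= divergence <= 0.2:
        raise ValueError("invalid parameters (need ω ≥ 0, n > 0, 0 ≤ divergence ≤ 0.2)")
    rng = random.Random(seed)
    sense = [
        a + b + c
        for a in BASES_STR
        for b in BASES_STR
        for c in BASES_STR
        if a + b + c not in STOP_CODONS
    ]
    ancestor = [sense[rng.randrange(len(sense))] for _ in range(n_codons)]
    seqs = [list(ancestor), list(ancestor)]
    target = round(divergence * 3 * n_codons)
    p_syn = min(1.0, 1.0 / omega_true) if omega_true > 0 else 1.0
    p_non = min(1.0, omega_true)
    applied = 0
    guard = 0
    while applied < target:
        guard += 1
        if guard > 1_000_000:
            raise RuntimeError("codon-pair simulation did not converge")
        lineage = rng.randrange(2)
        site = rng.randrange(3 * n_codons)
        ci, off = divmod(site, 3)
        cur = seqs[lineage][ci]
        alt = [b for b in BASES_STR if b != cur[off]]
        mut = cur[:off] + alt[rng.randrange(3)] + cur[off + 1 :]
        if mut in STOP_CODONS:
            continue
        p = p_syn if translate(mut) == translate(cur) else p_non
        if p >= 1.0 or rng.random() < p:
            seqs[lineage][ci] = mut
            applied += 1
    cds1, cds2 = "".join(seqs[0]), "".join(seqs[1])
    realized = sum(a != b for a, b in zip(cds1, cds2)) / (3 * n_codons)
    truth = GroundTruth(true_omega=omega_true, realized_divergence=realized)
    return (cds1, cds2), truth
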