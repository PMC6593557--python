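"""Cluster motif hits and rank transcripts as candidate tra-like genes.

The discovery logic: a genuine TRA/TRA-2 autoregulatory cluster shows up
as several elements packed into a few hundred bases of one transcript,
between exons that encode an SR-rich protein. Candidates are ordered by
(total hits, best-cluster size, best-cluster density), all descending,
with transcript id as a deterministic tie-break. The SR-ORF check is a
flag, not a filter, so dsx-/fru-like targets stay visible in the report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from sdscan import domains as domains_mod
from sdscan.motif import MotifHit, MotifModel, scan_sequence
from sdscan.seq_io import SequenceRecord, find_orfs


@dataclass(frozen=True)
class SiteCluster:
    """A gap-bounded group of element occurrences on one sequence.

    ``span`` is measured core-to-core: last core_end − first core_start.
    """

    seq_id: str
    hit_indices: tuple[int, ...]
    n_elements: int
    span: int
    density: float


@dataclass(frozen=True)
class CandidateReport:
    seq_id: str
    length: int
    total_hits: int
    best_cluster: SiteCluster | None
    sr_orf_found: bool
    sr_pct: float | None
    rank: int


def call_clusters(
    hits: Sequence[MotifHit], min_elements: int = 3, max_gap: int = 150
) -> list[SiteCluster]:
    """Single-linkage grouping of hits by core_start gaps ≤ ``max_gap``.

    Groups smaller than ``min_elements`` are discarded. Hits must lie on
    one sequence and be sorted by core_start (the scanner's order).
    """
    if not hits:
        return []
    seq_ids = {h.seq_id for h in hits}
    if len(seq_ids) > 1:
        raise ValueError(f"hits span multiple sequences: {sorted(seq_ids)}")
    starts = [h.core_start for h in hits]
    if starts != sorted(starts):
        raise ValueError("hits must be sorted by core_start")

    clusters = []
    group = [0]
    for i in range(1, len(hits)):
        if hits[i].core_start - hits[i - 1].core_start <= max_gap:
            group.append(i)
        else:
            clusters.extend(_emit(hits, group, min_elements))
            group = [i]
    clusters.extend(_emit(hits, group, min_elements))
    return clusters


def _emit(hits: Sequence[MotifHit], group: list[int], min_elements: int):
    if len(group) < min_elements:
        return
    span = hits[group[-1]].core_end - hits[group[0]].core_start
    yield SiteCluster(
        seq_id=hits[group[0]].seq_id,
        hit_indices=tuple(group),
        n_elements=len(group),
        span=span,
        density=len(group) / span,
    )


def best_cluster(clusters: Sequence[SiteCluster]) -> SiteCluster | None:
    if not clusters:
        return None
    return max(clusters, key=lambda c: (c.n_elements, c.density))


def rank_candidates(
    transcriptome: Sequence[SequenceRecord],
    model: MotifModel | None = None,
    min_elements: int = 3,
    max_gap: int = 150,
    min_codons: int = 50,
    sr_threshold: float = 25.0,
) -> list[CandidateReport]:
    """Scan every transcript and return reports ordered best-first (rank 1 = best)."""
    if not transcriptome:
        raise ValueError("empty transcriptome")
    model = model or MotifModel()
    rows = []
    for rec in transcriptome:
        hits = scan_sequence(rec, model, strands="forward")
        clusters = call_clusters(hits, min_elements=min_elements, max_gap=max_gap)
        best = best_cluster(clusters)
        sr_found, sr_pct = _sr_orf_check(rec, min_codons, sr_threshold)
        rows.append(
            CandidateReport(
                seq_id=rec.id,
                length=len(rec),
                total_hits=len(hits),
                best_cluster=best,
                sr_orf_found=sr_found,
                sr_pct=sr_pct,
                rank=0,
            )
        )
    rows.sort(key=_sort_key)
    return [
        CandidateReport(
            seq_id=r.seq_id,
            length=r.length,
            total_hits=r.total_hits,
            best_cluster=r.best_cluster,
            sr_orf_found=r.sr_orf_found,
            sr_pct=r.sr_pct,
            rank=i + 1,
        )
        for i, r in enumerate(rows)
    ]


def _sort_key(r: CandidateReport):
    n = r.best_cluster.n_elements if r.best_cluster else 0
    dens = r.best_cluster.density if r.best_cluster else 0.0
    return (-r.total_hits, -n, -dens, r.seq_id)


def _sr_orf_check(rec: SequenceRecord, min_codons: int, sr_threshold: float):
    """True (with the best domain pct) when some ORF carries an RS domain above threshold."""
    best_pct: float | None = None
    for orf in find_orfs(rec, min_codons=min_codons):
        for dom in domains_mod.find_rs_domains(orf.protein, threshold_pct=sr_threshold):
            if best_pct is None or dom.pct_rs > best_pct:
                best_pct = dom.pct_rs
    return (best_pct is not None), best_pct


def report_rows(reports: Sequence[CandidateReport]) -> list[dict]:
    """TSV-ready rows for the discovery report."""
    rows = []
    for r in reports:
        rows.append(
            {
                "rank": r.rank,
                "seq_id": r.seq_id,
                "length": r.length,
                "total_hits": r.total_hits,
                "cluster_n": r.best_cluster.n_elements if r.best_cluster else 0,
                "cluster_span": r.best_cluster.span if r.best_cluster else 0,
                "density": round(r.best_cluster.density, 6) if r.best_cluster else 0.0,
                "sr_orf_found": r.sr_orf_found,
                "sr_pct": round(r.sr_pct, 2) if r.sr_pct is not None else "",
            }
        )
    return rows
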