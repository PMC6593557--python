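"""RS-domain annotation and composition reports for SR proteins.

The operational rule for an RS (arginine/serine-rich) domain: take the
span from the first RS-or-SR dipeptide to the last one, and call it a
domain only when strictly more than ``threshold_pct`` (default 25%) of
the residues in that span are R or S. An optional ``split_on_gap`` mode
first groups dipeptides separated by at most ``max_gap_aa`` residues and
applies the rule per group, which models proteins with two RS domains
flanking an RRM (e.g. TRA-2).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class RSDomain:
    """An RS domain span, 0-based half-open on the protein."""

    start: int
    end: int
    pct_rs: float
    n_dipeptides: int


@dataclass(frozen=True)
class CompositionReport:
    pct_rs_global: float
    pct_proline: float
    rs_domains: list


@dataclass(frozen=True)
class OrfStatus:
    isoform_id: str
    status: str  # "full" | "truncated"
    protein_length: int
    truncation_fraction: float


def _dipeptide_starts(protein: str) -> list[int]:
    """Start indices of every RS or SR dipeptide (overlaps allowed)."""
    return [
        i
        for i in range(len(protein) - 1)
        if protein[i : i + 2] in ("RS", "SR")
    ]


def _span_stats(protein: str, start: int, end: int) -> tuple[float, int]:
    span = protein[start:end]
    # X counts toward span length but never as R or S
    rs = sum(1 for aa in span if aa in "RS")
    pct = 100.0 * rs / len(span)
    n_dip = sum(1 for i in range(start, end - 1) if protein[i : i + 2] in ("RS", "SR"))
    return pct, n_dip


def find_rs_domains(
    protein: str,
    threshold_pct: float = 25.0,
    segmentation: str = "single_span",
    max_gap_aa: int = 40,
) -> list[RSDomain]:
    """Call RS domains on a protein (no internal stops allowed).

    Returns an empty list when no RS/SR dipeptide exists or the candidate
    span(s) fail the strict > threshold rule.
    """
    if "*" in protein:
        raise ValueError("protein contains internal stop '*'")
    if segmentation not in ("single_span", "split_on_gap"):
        raise ValueError(f"unknown segmentation {segmentation!r}")
    dips = _dipeptide_starts(protein)
    if not dips:
        return []

    if segmentation == "single_span":
        groups = [dips]
    else:
        groups = [[dips[0]]]
        for d in dips[1:]:
            # gap = residues strictly between the end of the previous dipeptide
            # and the start of this one
            if d - (groups[-1][-1] + 2) <= max_gap_aa:
                groups[-1].append(d)
            else:
                groups.append([d])

    out = []
    for group in groups:
        start, end = group[0], group[-1] + 2
        pct, n_dip = _span_stats(protein, start, end)
        if pct > threshold_pct:
            out.append(RSDomain(start=start, end=end, pct_rs=pct, n_dipeptides=n_dip))
    return out


def composition(protein: str, threshold_pct: float = 25.0) -> CompositionReport:
    """Global R+S and proline percentages plus RS-domain calls."""
    if not protein:
        raise ValueError("empty protein")
    n = len(protein)
    return CompositionReport(
        pct_rs_global=100.0 * sum(1 for aa in protein if aa in "RS") / n,
        pct_proline=100.0 * protein.count("P") / n,
        rs_domains=find_rs_domains(protein, threshold_pct=threshold_pct),
    )


def classify_orf(
    isoform_protein: str,
    reference_protein: str,
    min_fraction: float = 0.5,
    isoform_id: str = "",
) -> OrfStatus:
    """Full vs prematurely-truncated call relative to a reference protein.

    ``truncated`` iff the isoform protein is strictly shorter than
    ``min_fraction`` of the reference length (141 aa vs 282 aa at the
    default 0.5 is still "full").
    """
    if not isoform_protein or not reference_protein:
        raise ValueError("proteins must be non-empty")
    frac = len(isoform_protein) / len(reference_protein)
    status = "truncated" if len(isoform_protein) < min_fraction * len(reference_protein) else "full"
    return OrfStatus(
        isoform_id=isoform_id,
        status=status,
        protein_length=len(isoform_protein),
        truncation_fraction=frac,
    )
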