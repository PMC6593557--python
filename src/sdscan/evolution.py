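"""Pairwise dN/dS (ω) estimation by Nei-Gojobori (1986) counting.

A desk-scale purifying-selection screen: protein-guided codon alignment
(back-threading a CDS pair through a given protein alignment) followed
by the NG86 estimator. Synonymous/nonsynonymous site fractions are
computed per codon from the standard nuclear code with stop-producing
single-base changes excluded from the denominator; codon pairs with
multiple differences are averaged over all minimal mutational pathways,
discarding pathways that pass through a stop codon. Proportions are
corrected for multiple hits with the Jukes-Cantor formula
d = −(3/4)·ln(1 − (4/3)·p), and ω = dN/dS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

from sdscan.seq_io import STOP_CODONS, translate

BASES = "ACGT"


@dataclass(frozen=True)
class CodonAlignment:
    """A pair of codon-aligned CDSs; gap columns are ('---', codon) etc."""

    ids: tuple
    codon_columns: tuple

    @property
    def n_ungapped(self) -> int:
        return sum(
            1
            for a, b in self.codon_columns
            if "-" not in a and "-" not in b
        )


@dataclass(frozen=True)
class DnDsEstimate:
    """NG86 counts and rates. ``None`` marks an undefined quantity
    (saturated p ≥ 3/4, or ω with dS = 0)."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float | None
    dN: float | None
    omega: float | None
    n_codons_used: int


def backthread(
    protein_alignment: tuple[str, str], cds_pair: tuple[str, str]
) -> CodonAlignment:
    """Thread a CDS pair through its protein alignment (codon alignment).

    Each CDS, gaps removed, must translate exactly to its protein row;
    a trailing stop codon on the CDS is tolerated and dropped.
    """
    columns: list[tuple[str, str]] = []
    rows = []
    for prot_aln, cds in zip(protein_alignment, cds_pair):
        prot = prot_aln.replace("-", "")
        cds = cds.upper()
        if len(cds) % 3 == 0 and cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        if len(cds) != 3 * len(prot):
            raise ValueError(
                f"CDS length {len(cds)} does not match protein length {len(prot)}"
            )
        trans = translate(cds)
        for pos, (a, b) in enumerate(zip(trans, prot)):
            if a != b and a != "X" and b != "X":
                raise ValueError(
                    f"translation mismatch at protein position {pos}: {a!r} != {b!r}"
                )
        codons = []
        i = 0
        for aa in prot_aln:
            if aa == "-":
                codons.append("---")
            else:
                codons.append(cds[3 * i : 3 * i + 3])
                i += 1
        rows.append(codons)
    if len(rows[0]) != len(rows[1]):
        raise ValueError("protein alignment rows have different lengths")
    columns = list(zip(rows[0], rows[1]))
    return CodonAlignment(ids=("seq1", "seq2"), codon_columns=tuple(columns))


# ---------------------------------------------------------------- NG86 counts


def codon_site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    Each position contributes one site, split by the fraction of its
    single-base changes that are synonymous; changes creating a stop
    codon are removed from that position's denominator.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = translate(codon)
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            n_valid += 1
            if translate(mutant) == aa:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


def pathway_differences(c1: str, c2: str) -> tuple[float, float] | None:
    """(Sd, Nd) between two sense codons, averaged over minimal pathways.

    Pathways passing through a stop codon are discarded; returns None if
    every ordering is stop-crossing (the column is then unusable).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    totals = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if translate(nxt) == translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:
        return None
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 distance −(3/4)·ln(1 − 4p/3); None when saturated (p ≥ 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def _usable(a: str, b: str) -> bool:
    return (
        "-" not in a
        and "-" not in b
        and "N" not in a
        and "N" not in b
        and a not in STOP_CODONS
        and b not in STOP_CODONS
    )


def ng86(aln: CodonAlignment) -> DnDsEstimate:
    """Nei-Gojobori estimate over the usable columns of a codon alignment.

    Columns with gaps, Ns or stops are dropped pairwise; so are the rare
    columns whose every mutational pathway crosses a stop.
    """
    S = N = Sd = Nd = 0.0
    used = 0
    for a, b in aln.codon_columns:
        if not _usable(a, b):
            continue
        path = pathway_differences(a, b)
        if path is None:
            continue
        sa, na = codon_site_fractions(a)
        sb, nb = codon_site_fractions(b)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        Sd += path[0]
        Nd += path[1]
        used += 1
    if used == 0:
        raise ValueError("no usable codon columns")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    omega: float | None
    if dS is None or dN is None or dS == 0.0:
        omega = None
    else:
        omega = dN / dS
    return DnDsEstimate(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, dS=dS, dN=dN, omega=omega,
        n_codons_used=used,
    )


def screen_domains(
    alignments: Sequence[tuple[str, CodonAlignment]]
) -> list[dict]:
    """One NG86 estimate per named domain alignment, TSV-ready.

    Undefined quantities are emitted as the string "undefined" so the
    flag survives a round-trip through a TSV report.
    """
    rows = []
    for name, aln in alignments:
        est = ng86(aln)
        rows.append(
            {
                "domain": name,
                "n_codons": est.n_codons_used,
                "S": round(est.S, 4),
                "N": round(est.N, 4),
                "Sd": round(est.Sd, 4),
                "Nd": round(est.Nd, 4),
                "pS": round(est.pS, 6),
                "pN": round(est.pN, 6),
                "dS": "undefined" if est.dS is None else round(est.dS, 6),
                "dN": "undefined" if est.dN is None else round(est.dN, 6),
                "omega": "undefined" if est.omega is None else round(est.omega, 6),
            }
        )
    return rows
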