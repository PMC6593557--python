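import itertools
import random
import statistics

import pytest
from hypothesis import given, settings, strategies as st

from sdscan import synthetic_data as synth
from sdscan.evolution import (
    CodonAlignment,
    backthread,
    codon_site_fractions,
    jukes_cantor,
    ng86,
    pathway_differences,
)
from sdscan.seq_io import STOP_CODONS, translate

SENSE_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS
]


def oracle_site_fractions(codon):
    """Independent recount of the per-position synonymous-site fractions."""
    syn = 0.0
    for pos in range(3):
        outcomes = []
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            outcomes.append(translate(mut) == translate(codon))
        if outcomes:
            syn += sum(outcomes) / len(outcomes)
    return syn, 3.0 - syn


def oracle_pathways(c1, c2):
    """Recursive enumeration of minimal mutational pathways, stops discarded."""
    if c1 == c2:
        return [(0.0, 0.0)]
    results = []
    for pos in range(3):
        if c1[pos] == c2[pos]:
            continue
        step = c1[:pos] + c2[pos] + c1[pos + 1 :]
        if step in STOP_CODONS:
            continue
        is_syn = translate(step) == translate(c1)
        for sd, nd in oracle_pathways(step, c2):
            results.append((sd + is_syn, nd + (not is_syn)))
    return results


def simple_alignment(cds1, cds2):
    cols = tuple(
        (cds1[i : i + 3], cds2[i : i + 3]) for i in range(0, len(cds1), 3)
    )
    return CodonAlignment(ids=("a", "b"), codon_columns=cols)


class TestBackthread:
    def test_no_gap_threading(self):
        aln = backthread(("MK", "MK"), ("ATGAAA", "ATGAAG"))
        assert aln.codon_columns == (("ATG", "ATG"), ("AAA", "AAG"))
        assert aln.n_ungapped == 2

    def test_gap_threading(self):
        aln = backthread(("M-K", "MAK"), ("ATGAAA", "ATGGCAAAA"))
        assert aln.codon_columns[1] == ("---", "GCA")

    def test_translation_mismatch_rejected(self):
        with pytest.raises(ValueError, match="position 1"):
            backthread(("MK", "MK"), ("ATGAAA", "ATGCCC"))

    def test_trailing_stop_tolerated(self):
        aln = backthread(("MK", "MK"), ("ATGAAATAA", "ATGAAG"))
        assert aln.n_ungapped == 2


class TestSiteCounts:
    @pytest.mark.parametrize("codon", SENSE_CODONS)
    def test_all_sense_codons_match_oracle(self, codon):
        got = codon_site_fractions(codon)
        expected = oracle_site_fractions(codon)
        assert got[0] == pytest.approx(expected[0])
        assert got[1] == pytest.approx(expected[1])
        assert got[0] + got[1] == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_site_fractions("TAA")


class TestPathways:
    @given(st.sampled_from(SENSE_CODONS), st.sampled_from(SENSE_CODONS))
    @settings(deadline=None, max_examples=200)
    def test_matches_pathway_oracle(self, c1, c2):
        got = pathway_differences(c1, c2)
        paths = oracle_pathways(c1, c2)
        if not paths:
            assert got is None
            return
        sd = statistics.mean(p[0] for p in paths)
        nd = statistics.mean(p[1] for p in paths)
        assert got[0] == pytest.approx(sd)
        assert got[1] == pytest.approx(nd)
        n_diff = sum(a != b for a, b in zip(c1, c2))
        assert got[0] + got[1] == pytest.approx(n_diff)


class TestNg86:
    def test_identical_sequences(self):
        cds = "".join(random.Random(0).choices(SENSE_CODONS, k=100))
        est = ng86(simple_alignment(cds, cds))
        assert est.Sd == est.Nd == 0.0
        assert est.dS == est.dN == 0.0
        assert est.omega is None

    def test_single_synonymous_difference(self):
        rng = random.Random(1)
        codons = rng.choices(SENSE_CODONS, k=100)
        cds1 = "".join(codons)
        mutated = codons.copy()
        mutated[40] = "AAG" if codons[40] != "AAG" else "AAA"
        codons[40] = "AAA"  # Lys; AAA->AAG is synonymous
        cds1 = "".join(codons)
        cds2 = "".join(mutated[:40] + ["AAG"] + mutated[41:])
        est = ng86(simple_alignment(cds1, cds2))
        assert est.Sd == 1.0 and est.Nd == 0.0
        assert est.dN == 0.0 and est.omega == 0.0

    def test_symmetry(self):
        (cds1, cds2), _ = synth.generate_codon_pair(0.5, 120, 0.1, seed=5)
        a = ng86(simple_alignment(cds1, cds2))
        b = ng86(simple_alignment(cds2, cds1))
        assert a.S == pytest.approx(b.S) and a.N == pytest.approx(b.N)
        assert a.Sd == pytest.approx(b.Sd) and a.Nd == pytest.approx(b.Nd)
        assert a.omega == pytest.approx(b.omega)

    def test_site_sum_invariant(self):
        (cds1, cds2), _ = synth.generate_codon_pair(0.3, 150, 0.1, seed=8)
        est = ng86(simple_alignment(cds1, cds2))
        assert est.S + est.N == pytest.approx(3 * est.n_codons_used, abs=1e-6)
        assert est.S > 0 and est.N > 0 and est.pS >= 0 and est.pN >= 0

    def test_gap_and_n_columns_dropped(self):
        aln = CodonAlignment(
            ids=("a", "b"),
            codon_columns=(("ATG", "ATG"), ("---", "AAA"), ("ANA", "AAA"), ("AAA", "AAA")),
        )
        est = ng86(aln)
        assert est.n_codons_used == 2

    def test_synonymous_tail_extension_preserves_omega(self):
        (cds1, cds2), _ = synth.generate_codon_pair(0.4, 100, 0.1, seed=9)
        base = ng86(simple_alignment(cds1, cds2))
        # appending an identical tail adds sites but no differences; omega
        # (ratio of corrected rates) must not increase sign or become negative
        tail = "GGTGGTGGT" * 10
        ext = ng86(simple_alignment(cds1 + tail, cds2 + tail))
        assert ext.Sd == base.Sd and ext.Nd == base.Nd
        assert ext.omega is not None and ext.omega >= 0

    def test_jukes_cantor_saturation(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.8) is None
        assert jukes_cantor(0.05) == pytest.approx(0.0517, abs=1e-3)


class TestRecovery:
    def test_mean_omega_recovered(self):
        ests = []
        for seed in range(12):
            (cds1, cds2), _ = synth.generate_codon_pair(0.5, 300, 0.05, seed=100 + seed)
            ests.append(ng86(simple_alignment(cds1, cds2)).omega)
        assert statistics.mean(ests) == pytest.approx(0.5, abs=0.15)
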