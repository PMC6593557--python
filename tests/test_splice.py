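import random

import pytest

from sdscan import synthetic_data as synth
from sdscan.seq_io import make_record
from sdscan.splice import (
    AlignmentFailure,
    SpliceJunctionError,
    build_gene_model,
    classify_events,
    score_splice_site,
    splice_by_model,
    spliced_align,
)


def _random_exon(rng, length):
    while True:
        s = "".join(rng.choice("ACGT") for _ in range(length))
        if "CAATCAAC" not in s and not s.endswith("G") and not s.startswith("G"):
            return s


class TestSplicedAlign:
    def test_two_exon_construction(self):
        rng = random.Random(7)
        e1, e2 = _random_exon(rng, 60), _random_exon(rng, 60)
        intron = "GT" + "".join(rng.choice("ACT") for _ in range(46)) + "AG"
        locus = make_record("L", e1 + intron + e2)
        cdna = make_record("c", e1 + e2)
        aln = spliced_align(cdna, locus)
        assert len(aln.blocks) == 2
        assert aln.introns == ((60, 110, "GT", "AG"),)
        assert aln.clipped_5p == aln.clipped_3p == 0

    def test_unspliced_identity(self):
        rng = random.Random(3)
        seq = _random_exon(rng, 400)
        aln = spliced_align(make_record("c", seq), make_record("L", seq))
        assert len(aln.blocks) == 1 and aln.introns == ()

    def test_terminal_overhang_clipped(self):
        rng = random.Random(5)
        seq = _random_exon(rng, 300)
        cdna = make_record("c", "TTAACCTTAACCTTAACCTT" + seq)
        aln = spliced_align(cdna, make_record("L", seq))
        assert aln.clipped_5p == 20 and aln.clipped_3p == 0

    def test_unalignable_fails(self):
        rng = random.Random(9)
        a = _random_exon(rng, 300)
        b = _random_exon(rng, 300)
        with pytest.raises(AlignmentFailure):
            spliced_align(make_record("c", a), make_record("L", b))

    def test_gt_ag_violation_reported(self):
        rng = random.Random(13)
        e1, e2 = _random_exon(rng, 60), _random_exon(rng, 60)
        intron = "CC" + "".join(rng.choice("ACT") for _ in range(46)) + "TT"
        locus = make_record("L", e1 + intron + e2)
        cdna = make_record("c", e1 + e2)
        with pytest.raises(SpliceJunctionError):
            spliced_align(cdna, locus)
        # without enforcement the intron is kept wherever anchoring put it
        aln = spliced_align(cdna, locus, enforce_gt_ag=False)
        (intron,) = aln.introns
        assert intron[1] - intron[0] == 50
        assert (intron[2], intron[3]) != ("GT", "AG")

    @pytest.mark.parametrize("seed", range(6))
    def test_synthetic_junction_recovery_exact(self, seed):
        locus, isoforms, truth = synth.generate_locus_with_isoforms(seed=seed)
        for rec in isoforms:
            name = rec.id.split("_")[0]
            aln = spliced_align(rec, locus)
            assert tuple((s, e) for s, e, *_ in aln.introns) == truth.true_junctions[name]
            assert all(i[2] == "GT" and i[3] == "AG" for i in aln.introns)
            # round trip: splicing the locus by the blocks reproduces the cDNA
            assert splice_by_model(locus.residues, aln) == rec.residues


class TestGeneModel:
    def test_single_alignment_four_exons(self, locus_set):
        locus, isoforms, _ = locus_set
        f1 = next(r for r in isoforms if r.id.startswith("F1"))
        model = build_gene_model([spliced_align(f1, locus)])
        assert len(model.exons) == 4 and len(model.introns) == 3

    def test_alternative_donor_recorded(self, locus_set):
        locus, isoforms, truth = locus_set
        by = {r.id.split("_")[0]: r for r in isoforms}
        model = build_gene_model(
            [spliced_align(by["F1"], locus), spliced_align(by["M1"], locus)]
        )
        ref_i2 = truth.true_junctions["F1"][1]
        alt_i2 = truth.true_junctions["M1"][1]
        assert ref_i2 in {(s, e) for s, e, *_ in model.introns}
        assert alt_i2 in {(s, e) for s, e, *_ in model.alt_introns}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_gene_model([])


class TestSiteScoring:
    def _locus_with_donor(self, nine):
        return make_record("L", "A" * 30 + nine + "A" * 30)

    def test_consensus_donor_scores_one(self):
        locus = self._locus_with_donor("CAGGTAAGT")
        s = score_splice_site(locus, 33, "donor")
        assert s.score == pytest.approx(1.0) and s.klass == "strong"

    def test_gc_donor_scores_zero(self):
        locus = self._locus_with_donor("CAGGCAAGT")
        s = score_splice_site(locus, 33, "donor")
        assert s.score == 0.0 and s.klass == "weak"

    def test_weak_donor_intermediate(self):
        locus = self._locus_with_donor("AAGGTATTT")
        s = score_splice_site(locus, 33, "donor")
        assert 0.0 < s.score < 1.0

    def test_consensus_acceptor_strong(self):
        locus = make_record("L", "A" * 20 + "TTTTTTTTTTACAG" + "G" + "A" * 20)
        s = score_splice_site(locus, 34, "acceptor")
        assert s.score == pytest.approx(1.0) and s.klass == "strong"

    def test_window_bounds_checked(self):
        with pytest.raises(ValueError):
            score_splice_site(make_record("L", "ACGTACGT"), 2, "donor")


class TestClassifyEvents:
    def test_five_isoform_ground_truth(self, locus_set):
        locus, isoforms, truth = locus_set
        alns = {r.id.split("_")[0]: spliced_align(r, locus) for r in isoforms}
        for name in ("F2", "F3", "M1", "M2"):
            events = classify_events(alns["F1"], alns[name])
            assert {e.event_type for e in events} == {truth.true_events[name]}, name
            assert len(events) == 1

    def test_intron_retention_coordinates(self, locus_set):
        locus, isoforms, truth = locus_set
        alns = {r.id.split("_")[0]: spliced_align(r, locus) for r in isoforms}
        (ev,) = classify_events(alns["F1"], alns["F3"])
        assert (ev.start, ev.end) == truth.true_junctions["F1"][1]

    def test_cassette_exon_detected(self, locus_set):
        locus, isoforms, truth = locus_set
        f1 = next(r for r in isoforms if r.id.startswith("F1"))
        ref = spliced_align(f1, locus)
        i1, i2, i3 = truth.true_junctions["F1"]
        # construct a skip isoform: exon 2 removed, introns 1+2 fused, intron 3 spliced
        skip = make_record(
            "skip",
            locus.residues[: i1[0]]
            + locus.residues[i2[1] : i3[0]]
            + locus.residues[i3[1] :],
        )
        alt = spliced_align(skip, locus)
        events = classify_events(ref, alt)
        assert [e.event_type for e in events] == ["cassette_exon"]
        assert (events[0].start, events[0].end) == (i1[1], i2[0])

    def test_different_loci_rejected(self, locus_set):
        locus, isoforms, _ = locus_set
        f1 = next(r for r in isoforms if r.id.startswith("F1"))
        aln = spliced_align(f1, locus)
        other = make_record("other_locus", locus.residues)
        aln2 = spliced_align(make_record("c", f1.residues), other)
        with pytest.raises(ValueError):
            classify_events(aln, aln2)
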