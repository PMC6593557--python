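# Methods

This note records the models, rules and numerical choices behind each
stage, what the synthetic generators do and do not emulate, and the
design decisions that were genuinely open.

## Motif model and scanning

The TRA/TRA-2 binding site is modelled as a 13-bp element with a fixed
anatomy: 4 variable upstream bases + an invariant 8-bp core
(`CAATCAAC`) + 1 variable downstream base. Scanning keys on the core
only; the context bases are annotation carried along for logo building.
This reflects the empirical picture in sand flies — complete core
conservation with variability confined to the flanks — and avoids
committing to a degenerate flank pattern that is not well determined.
A `brachycera_13mer` preset accepts IUPAC-degenerate context patterns
for scans of taxa where the flanks are informative.

Choices that matter:

* **Overlaps are reported.** The core self-overlaps at shift 7
  (`CAATCAACAATCAAC` contains two cores); silently suppressing
  overlapping matches would bias cluster counts.
* **`N` never matches.** Assembly gaps cannot create hits.
* **Mismatch budget defaults to 0.** The core is invariant in the taxa
  this element model targets; the budget is configurable for
  exploratory scans and the scanner is oracle-tested for budgets up
  to 2.
* Minus-strand hits (genomic scans) are reported in forward
  coordinates; transcript scans default to the forward strand because
  the element functions in the pre-mRNA sense.

Logo columns report raw counts, frequencies, and information content
`IC = 2 − H` bits, with Shannon entropy `H` computed from observed
frequencies, no pseudocounts and no small-sample correction: the
intended use is describing dozens of aligned elements, not database-
scale PWM inference. Elements clipped by a sequence end are excluded
from the profile.

## Clustering and candidate ranking

Hits are grouped by single linkage on core-start gaps ≤ `max_gap`
(default 150 bp); groups below `min_elements` (default 3) are
discarded. The 150 bp default derives from the densest observed
cluster in the motivating data — six elements spanning ~324 bp, i.e.
a mean core-start spacing near 65 bp — with a generous slack factor;
it is a screening parameter, not a biological constant. Cluster span
is measured core-to-core, so context bases never change cluster
geometry.

Candidates are ordered by the descending lexicographic key
(total hits, best-cluster size, best-cluster density), with transcript
id as the final deterministic tie-break. Raw count and clustering are
combined rather than either alone: count is the primary discovery
signal, clustering separates a genuine regulatory array from scattered
chance matches of equal count. The SR-ORF check (any ORF of ≥ 50
codons with an RS domain above 25% R+S) is reported as a flag rather
than used as a filter, so that downstream targets such as *dsx*/*fru*
— which carry clusters but encode non-SR proteins in the scanned
region — stay visible in the same report.

The 50-codon ORF floor is this package's choice (the motivating study
does not state one); it is small enough to keep a severely truncated
SR ORF detectable and large enough to skip spurious micro-ORFs.

## RS domains and ORF status

The RS-domain rule is literal: candidate span from the first
`RS`/`SR` dipeptide to the last, called a domain iff strictly more
than `threshold` (default 25) percent of the span's residues are R or
S. The denominator is the full span including both terminal
dipeptides. An optional `split_on_gap` mode first groups dipeptides
separated by ≤ 40 aa and applies the rule per group; this models
proteins with two RS domains flanking an RRM (TRA-2-like
architectures) where a single first-to-last span would dilute both
below threshold. The 40-aa gap default approximates an RRM-plus-linker
spacer; it is configurable because no published segmentation rule
exists. `X` residues count toward span length but never toward
R/S/P tallies (conservative on gappy assemblies).

An isoform ORF is called `truncated` when its protein is strictly
shorter than 0.5 × the reference protein (the fully spliced isoform's
product). The strict inequality makes the half-length boundary "full".

## Spliced alignment

The aligner is deliberately exact (no substitutions inside blocks):
its use case is cDNA clones against a genomic amplicon from the same
colony, where apparent mismatches are more likely junction artifacts
than polymorphism. This buys a hard invariant — splicing the locus by
the reconstructed blocks reproduces the aligned cDNA segment byte for
byte — which the tests enforce as a round trip.

Algorithm: (1) all maximal exact k-mer matches (k = 15) become
anchors; (2) dynamic programming selects the highest-coverage
collinear chain, requiring cDNA contiguity after trimming anchor
overlaps and locus gaps ≥ `min_intron` (30 bp, the shortest intron
class expected here); ties prefer fewer introns so repeats never
inflate intron counts; (3) each junction is slid within its ambiguity
interval (positions where the spliced product is unchanged) to a
GT..AG placement, taking the left-most compliant shift for
determinism; (4) terminal cDNA bases not placeable on the locus (UTR
overhangs beyond an amplicon) are reported as clipped, never forced.
Failure modes are explicit errors: chain coverage < 50% of the cDNA,
or no GT-AG placement at some junction under enforcement (the caller
may retry unenforced, e.g. for non-canonical introns).

Gene models merge isoform alignments on one locus: exons are the union
of blocks split at every distinct junction; the most-spliced isoform
defines the reference intron set and every other distinct intron is
recorded as an alternative (capturing alternative donors/acceptors).

Splice-site strength uses a fixed canonical metazoan consensus weight
table (donor `MAG|GTRAGT`, acceptor = 10-base polypyrimidine tract +
`NCAG|G`), not species-trained PWMs: the qualitative weak/strong
distinction is what the biology needs, and a trained model would imply
precision the data cannot support. Scores are mean per-position
agreement in [0,1]; the GT/AG dinucleotides are mandatory (score 0
when absent); `strong` means score ≥ 0.7.

## Event classification

Relative to a reference isoform, each reference intron is looked up in
the alternative: same coordinates → shared; same acceptor/different
donor → `alt_donor_5p`; same donor/different acceptor →
`alt_acceptor_3p`; absent and fully exonic in the alternative →
`intron_retention`; one alternative intron exactly fusing two or more
reference introns → `cassette_exon` per skipped exon; an alternative
with no introns at all against a reference with ≥ 1 → a single
`unspliced` event. Coordinates are the affected locus region (the
differing donor/acceptor stretch, the retained intron, or the skipped
exon).

## dN/dS screening

The estimator is Nei–Gojobori (1986) counting. Per sense codon, each
position contributes one site split by the fraction of its single-base
changes that are synonymous, with stop-producing changes removed from
that position's denominator (so S + N = 3 per codon exactly). Sites
are averaged over the two sequences. Codon pairs differing at several
positions are averaged over all minimal mutational pathways, with
stop-crossing pathways discarded; in the (rare) case that every
pathway crosses a stop the column is excluded. Proportions pS, pN are
corrected with Jukes–Cantor, `d = −(3/4)·ln(1 − 4p/3)`, undefined at
saturation (p ≥ 3/4); ω = dN/dS is undefined when dS = 0 or either
rate is undefined, and the reports flag rather than coerce such
values. Gap- or N-containing columns are dropped pairwise.

A counting estimator is not a maximum-likelihood branch model: it
yields one pairwise ω, cannot attribute rate variation to specific
tree branches or sites, and is biased at high divergence. It is used
here as a screening statistic for the qualitative claim ω ≪ 1
(purifying selection) on domain-restricted alignments, where it is
accurate: simulation recovery at 300 codons shows mean errors < 0.05
across ω ∈ {0.1, 0.5, 1.0}.

## Synthetic data

The generators produce the structures the analysis assumes, with
ground truth validated at generation time by running the corresponding
analysis stage, and full determinism given the seed.

* **Transcriptome**: background transcripts with log-normal lengths
  (median 1.5 kb, σ = 0.35) and 40% GC, rejection-sampled to contain
  zero cores on either strand so planted-recovery expectations are
  exact. The planted transcript is the retained-intron isoform of a
  generated locus: SR-rich exons around an intron carrying the element
  cluster — the same signature the discovery step screens for. A
  core-free background is an idealization: real transcriptomes contain
  chance cores (≈ 2% of 1.5-kb transcripts carry one), so real
  screens rank the planted signal against a nonzero noise floor;
  passing tests demonstrate correctness of the machinery, not the
  statistical power of the screen on real data.
* **Locus**: four exons / three introns, all GT..AG. Default exon CDS
  sizes (30, 30, 60, 60 codons) put the canonical-ORF truncation of
  every variant isoform below the 0.5 classification threshold.
  Intron 2 (500 bp) carries six elements with core starts spaced
  55–70 bp (expected span ≈ 320 bp, emulating the observed ~324 bp
  cluster), an alternative donor ~232 bp downstream of exon 2, an
  alternative acceptor retaining the final 100 bp, and in-frame stop
  codons at the start of every retained segment. The five isoforms
  realize: fully spliced (F1), alternative 3' acceptor (F2), intron
  retention (F3), alternative 5' donor (M1), unspliced (M2).
  Junction edges are built ambiguity-free (the exon base flanking each
  intron never equals the intron base at the opposite end), so true
  junctions are the unique GT-AG placement and recovery can be scored
  exactly. Real loci do contain ambiguous junctions; for them the
  aligner's left-most-GT-AG rule is a convention, not a recovery
  guarantee. Assembly draws that create a chance core across a
  junction are rejected and redrawn deterministically.
* **Codon pairs**: two lineages from a random sense-codon ancestor;
  mutations proposed uniformly over positions and bases, synonymous
  proposals accepted with probability min(1, 1/ω), nonsynonymous with
  min(1, ω), stop-creating proposals rejected, until the requested
  divergence (subs/site, ≤ 0.2) is realized exactly. The proposal
  process matches the mutational-opportunity model the NG86 estimator
  assumes (uniform base exchange), which is what makes unbiased
  recovery a meaningful test; it does not emulate transition/
  transversion bias or codon-usage bias.

## Problem sizes in tests and the acceptance script

Recovery claims are computed at: 20 transcriptomes × 501 transcripts
(planted recovery, false clusters), 20 generic loci with 1–4 introns
of 30–500 bp (junction recovery), 20 five-isoform loci (event labels),
and 50 replicate codon pairs of 300 codons per ω value. The
three-point ω-recovery check uses divergence 0.15: with ~45 expected
synonymous differences the ratio estimator's small-count bias is
negligible, whereas at divergence 0.05 (~11 expected synonymous
differences) the ω = 1 estimate is upward-biased by Jensen's
inequality alone — that regime is still exercised, as the
ordering-preservation check (ω 0.1 vs 0.6 at divergence 0.05).

## Known limitations

* The scanner is pattern-based; degenerate elements (e.g. mosquito
  sites with an eroded core) need the IUPAC preset or a mismatch
  budget, and counts are then threshold-sensitive.
* The spliced aligner has no mismatch tolerance and is not suitable
  for cross-individual or cross-species alignment, nor for
  genome-scale input (anchor indexing is in-memory and quadratic
  chaining assumes few anchors).
* Splice-site scores are a fixed consensus heuristic in [0,1]; they
  are comparable within a locus, not calibrated probabilities.
* Pairwise counting ω cannot reproduce branch- or site-specific
  selection inference; it screens, it does not test hypotheses about
  lineages.
* `split_on_gap` RS-domain segmentation approximates unspecified
  published delimitations; alignment-dependent domain boundaries are
  not reproduced.
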