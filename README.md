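# sdscan

Discovery and characterization of *transformer*-like sex-determination
genes from transcriptome assemblies.

## The problem

In most insects the gene *transformer* (*tra*) sits at the heart of sex
determination: its female-specific splice form encodes an SR
(serine/arginine-rich) splicing activator that, with TRA-2, maintains
its own female splicing and drives the female-specific splicing of
*doublesex* (*dsx*) and *fruitless* (*fru*). The catch for gene
discovery is that TRA evolves so fast that sequence homology searches
(BLAST and relatives) routinely fail even between related species.

The signature that *does* survive is regulatory: TRA/TRA-2 complexes
bind a ~13-bp RNA repeat element (the *dsx* repeat element) that occurs
in clusters, and a *tra* gene that autoregulates carries such a cluster
inside its own sex-specifically spliced intron, flanked by exons
encoding SR-rich protein. `sdscan` turns that signature into a
screening pipeline:

1. **motif** — scan transcripts for the element, which in sand flies
   carries an invariant 8-bp core `CAATCAAC` inside the 13-mer;
   build per-column count/information-content profiles (sequence-logo
   tables) of the matched elements.
2. **cluster_rank** — group hits into clusters (≥ 3 elements, core
   starts ≤ 150 bp apart by default) and rank all transcripts by
   (total hits, cluster size, cluster density), flagging transcripts
   whose ORFs carry an RS domain.
3. **domains** — RS-domain annotation: span from the first to the last
   `RS`/`SR` dipeptide, called a domain when strictly more than 25% of
   its residues are R or S; plus proline content and full-vs-truncated
   ORF classification.
4. **splice** — exact spliced alignment of cDNA isoforms to a genomic
   locus (k-mer anchor chaining + GT-AG junction placement), merged
   gene models, donor/acceptor strength scores against a canonical
   consensus, and classification of alternative-splicing events
   (alt 5' donor, alt 3' acceptor, intron retention, cassette exon,
   unspliced).
5. **evolution** — protein-guided codon alignment and pairwise dN/dS
   (ω) by the Nei–Gojobori (1986) counting method with Jukes–Cantor
   correction, for purifying-selection screens (ω ≪ 1).
6. **synthetic_data** — seeded generators for all of the above with
   machine-readable ground truth: core-free background transcriptomes
   with a planted *tra*-like transcript, multi-isoform loci realizing
   the five splice-variant classes, and codon pairs evolved at a
   controlled ω.

## Worked example

Generate a synthetic transcriptome (500 background transcripts plus one
planted *tra*-like transcript) and run discovery:

```bash
sdscan simulate transcriptome --seed 1 --out sim/
sdscan discover --fasta sim/transcriptome.fasta --out report.tsv --bed hits.bed
head -3 report.tsv
```

```
rank	seq_id	length	total_hits	cluster_n	cluster_span	density	sr_orf_found	sr_pct
1	planted_seed1	1106	6	6	315	0.019048	True	100.0
2	bg00000_seed1	1855	0	0	0	0.0	False
```

The planted transcript ranks first: it is the only transcript carrying
element hits (6), they form a single cluster (315 bp span at this seed,
matching the designed ~320 bp geometry), and one of its ORFs contains an
RS domain (here a 100% R+S stretch). The same ranking logic applied to a
real assembly surfaces candidate *tra* transcripts for downstream
gene-model work:

```bash
sdscan simulate locus --seed 1 --out simlocus/
sdscan splice-map --cdna simlocus/isoforms.fasta --locus simlocus/locus.fasta --gff3 model.gff3
sdscan events --cdna simlocus/isoforms.fasta --locus simlocus/locus.fasta \
    --reference F1_seed1 --out events.tsv
cat events.tsv
```

```
reference	alternative	event	start	end
F1_seed1	F2_seed1	alt_acceptor_3p	672	773
F1_seed1	F3_seed1	intron_retention	273	773
F1_seed1	M1_seed1	alt_donor_5p	273	505
F1_seed1	M2_seed1	unspliced	123	1013
```

Each line classifies how one isoform differs from the fully spliced
female form: F2 uses an acceptor inside intron 2 (retaining its last
100 bp), F3 retains intron 2 entirely, M1 uses a donor ~230 bp
downstream of exon 2, and M2 is unspliced — the isoform taxonomy of an
autoregulating *tra* locus.

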