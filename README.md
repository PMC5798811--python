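# orgweaver

Isolation-free assembly of plant organellar genomes from whole-genome
shotgun data, plus the comparative toolkit that usually follows it.

## The problem

A plant cell carries one nuclear genome and hundreds of copies of its
chloroplast (cp) and mitochondrial (mt) genomes. When *total* DNA is
shotgun-sequenced, that copy-number difference shows up directly in the
mean read depth of the assembled contigs: nuclear contigs sit at ~1–2×,
mitochondrial contigs at roughly 50–100×, chloroplast contigs above 100×.
orgweaver exploits this to assemble complete circular organellar genomes
**without isolating organellar DNA at the bench** — the step that makes
traditional organelle sequencing slow and failure-prone.

It is aimed at people assembling cp/mt genomes of non-model plants from
one lane of long-read pyrosequencing-style data (plus accurate short reads
for polishing), and at anyone who needs the downstream comparisons:
base composition, quadripartite architecture, gene content, and a
multi-gene phylogeny.

## The method

Starting from an assembler's contigs and its contig-graph file (the
`454ContigGraph.txt` dialect: a contig-statistics section, then `C` edge
lines giving *left contig, 5′/3′ end, right contig, 5′/3′ end, edge
depth*):

1. **Depth binning.** Contig *i* with mean depth *d_i* is classed
   cp if *d_i* > 100, mt if 50 ≤ *d_i* ≤ 100, nuclear otherwise
   (thresholds adjustable to the sample).
2. **Graph restriction.** The end-polarity graph is cut down to one bin.
   In the mt graph, cp-depth contigs adjacent to mt contigs are kept as
   "cp-like" nodes — chloroplast-to-mitochondrion DNA transfer makes them
   genuine mitochondrial sequence at chloroplast stoichiometry.
3. **False-link removal.** Edges spanned by < 2 reads, or joining contigs
   whose depths differ by more than 3× (after dividing by the contig's
   estimated copy number — a collapsed repeat legitimately carries
   *k* × the baseline depth), are discarded.
4. **Multiplicity.** Copy number of contig *i* is
   max(1, round(*d_i* / median bin depth)).
5. **Traversal.** From the first bin contig in file order, the path
   extends greedily from both ends; at a fork the deepest compatible edge
   wins; a walk that returns to the seed's open end is a circle; a repeat
   may be revisited up to its copy number, but only when the path would
   otherwise break. Graphs containing collapsed repeats admit several
   edge-consistent closures (recombination isomers); orgweaver emits the
   **master circle** — the depth-maximal closed walk.
6. **Gap filling.** Remaining gaps are closed by a word-size-9 lookup
   index over the raw reads: reads matching a gap flank (seeded local
   alignment, +1/−2 match/mismatch, −3/−1 gap open/extend, E-value-style
   score cutoff) extend the flank by per-column majority consensus,
   iterating until the flanks overlap ≥ 40 bp at ≥ 95% identity.
7. **Polishing.** Accurate short reads are mapped back by exact seed +
   edit-distance verification (≤ 2 edits, substitutions or the
   single-base homopolymer indels typical of pyrosequencing); every
   pileup column where a ≥ 60% majority at depth ≥ 3 disagrees with the
   draft is corrected.
8. **Comparative stage.** Base composition and windowed GC; N50 and
   reference coverage; detection of the chloroplast quadripartite
   structure (LSC + IRa + SSC + IRb with IRb = revcomp(IRa)); and a
   phylogeny from 15 conserved mitochondrial protein-coding genes
   (*atp1, atp9, ccmB, cob, cox1, cox3, nad1, nad3, nad4, nad4L, nad6,
   nad7, nad9, rps3, rps4*): per-gene center-star alignment, gap columns
   removed, concatenation, p-distance, neighbor joining, bootstrap
   support by column resampling.

A first-class synthetic-fixture generator (`orgweaver.synthetic`) emulates
all of this end to end — quadripartite cp genomes, mt genomes with
dispersed repeats and a cp-derived insertion, depth-banded contig
fragmentation with correct 5′/3′ edge polarities, and reads whose dominant
error is homopolymer indels — so the whole pipeline is testable with no
downloads.

## Worked example

```bash
weaver simulate --seed 42 --out fixture        # synthetic study
weaver bin --graph fixture/454ContigGraph.txt --out bins.tsv
weaver assemble --graph fixture/454ContigGraph.txt \
    --contigs fixture/contigs.fasta --bin cp \
    --out cp_path.tsv --fasta cp_draft.fasta
weaver stats --fasta cp_draft.fasta --circular --out cp_stats.tsv
```

`bins.tsv` begins:

```
contig_id   depth     bin
1           129.891   CP
3           124.514   CP
8           75.4406   MT
```

— contigs 1 and 3 exceed the 100× chloroplast cutoff, contig 8 falls in
the 50–100× mitochondrial band. `weaver assemble` reports

```
1 path(s); circular: 1; unused contigs: 0
```

a single circular chloroplast path, and `cp_stats.tsv` gives the
reconstructed genome's statistics:

```
-                N50    150000
path0_circular   A%     27.34
path0_circular   T%     27.19
path0_circular   C%     22.68
path0_circular   G%     22.79
path0_circular   LSC    131616..66616 (85000 bp)
path0_circular   IRa    66616..91616  (25000 bp)
path0_circular   SSC    91616..106616 (15000 bp)
path0_circular   IRb    106616..131616 (25000 bp)
```

The A+T bias (~54.5%) and the quadripartite partition (85 kb LSC, two
25 kb inverted repeats, 15 kb SSC) match the planted architecture — the
reconstruction is exact up to the rotation of the circle.

`weaver gapfill`, `weaver polish` and `weaver phylo` cover the remaining
stages; every subcommand is a thin wrapper over the `orgweaver.*` modules,
which are the primary interface for scripted use.

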