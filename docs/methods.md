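# Methods

This note documents the models and procedures implemented in orgweaver,
the defaults and why they are set where they are, what the synthetic
generator does and does not emulate, and the numerical conventions.

## Depth binning

Organellar copy number per cell makes mean contig read depth a
near-separable classifier in total-DNA shotgun assemblies. The rule is a
fixed threshold partition: chloroplast strictly above `cp_min` (default
100×), mitochondrial inside the closed interval `[mt_min, mt_max]`
(default [50, 100]×), nuclear otherwise. The boundary convention —
CP strict, MT closed — resolves the ambiguity at exactly 100× in favor of
the mitochondrial bin. The thresholds are parameters because the bands
shift with sequencing depth and tissue (plastid content of leaf tissue is
far higher than of roots); `depth_histogram` exists to choose them by
eye on real data. No attempt is made to separate nuclear repeats that
reach organellar depth — that disambiguation happens structurally, during
traversal, where such contigs dead-end.

## The contig graph and its traversal

Edges carry end polarity: `(A, 3′) — (B, 5′)` means reads run off the
3′ end of A into the 5′ end of B. A forward-oriented contig is entered
at 5′ and exited at 3′; reversed, the converse. This makes a walk's
orientation bookkeeping purely local.

**Pruning.** Edges with `edge_depth < 2` (default) are noise. Edges whose
endpoint depths differ by a factor > 3 (default) join different genomes —
unless one endpoint is a collapsed repeat, whose depth is legitimately a
multiple of the baseline. A contig's copy number is
`max(1, round_half_up(depth / median bin depth))`. The multiplicity
rescue in pruning is limited to copy numbers ≤ 2 (`max_rescue_copies`):
dispersed organellar repeats are overwhelmingly two-copy, while a
contig estimated at 5–7 copies is far more plausibly a nuclear repeat
family or chloroplast contamination, and rescuing it would make the
depth-ratio filter vacuous (any ratio can be "explained" by a large
enough integer). Copy numbers themselves are not capped — traversal may
visit a 3-copy repeat three times; only the pruning rescue is bounded.

**Traversal.** Seeds are taken in contig file order (the assembler's
output order; `longest` is offered as an alternative policy because file
order is assembler-dependent). The seed is placed forward and the path
extended from both tips. At each tip, candidate edges leave the tip's
open end; the ranking is (edge depth, partner length, lexicographic
partner id), all descending except the id — every tie-break is
deterministic, and the module contains no randomness. Precedence at a
tip is:

1. extend to an unvisited contig (best-ranked candidate);
2. otherwise close the circle, if an edge returns to the path's opposite
   open end;
3. otherwise revisit a contig with spare copies — so a repeat's second
   visit happens only when the path would otherwise break, which stops
   depth-inflated nuclear repeats from being walked in circles;
4. otherwise the tip is a breakpoint.

A breakpoint leaves a linear path; the next unvisited bin contig seeds a
new path until none remain.

**Repeats and the master circle.** A graph with a collapsed two-copy
repeat admits multiple edge-consistent closures — exactly the
recombination-isomer ambiguity of plant mitochondrial genomes. A greedy
walk cannot decide locally which exit of a repeat leads to the master
circle rather than a premature subcircle. When any contig has copy
number > 1 (and the graph has ≤ 64 edges), the seed's path is therefore
found by bounded depth-first search over fork choices, keeping the
closed walk with the maximal total edge depth (the master circle: it
uses a superset of any subcircle's edges, all depths being positive).
The state budget (50 000 expansions) is never approached on organellar
graphs, which have a handful of forks; if it were exhausted the code
falls back to the greedy walk. Alternative isomers are not emitted as
sequences; they remain visible as unused edges in the report.

**cp-like contigs.** In the mitochondrial graph, chloroplast-binned
contigs adjacent to an mt contig are retained ("CP_LIKE") because
cp→mt transfer is common; they are walked but never seeded, and keep
their label in reports.

**Reference-guided ordering** (the conserved-chloroplast shortcut)
anchors each contig to a related genome by unique shared 21-mers, orders
by anchor midpoint, orients by majority strand, and flags unanchored
contigs and uncovered junctions. Contigs lying entirely inside an
inverted repeat anchor equally well to either IR copy; either placement
yields the same genome sequence, so outputs are compared at sequence
level, not contig-id level. Anchor hits spanning more than twice the
contig length indicate a contig wrapping the circular origin; its tail
hits are unwrapped before computing the span.

## Gap filling

A lookup table indexes every k-mer (default k = 9, the classic nucleotide
search word size) of every raw read. `search` seeds on shared words and
scores candidate reads by exact local alignment under +1/−2 match/
mismatch and −3/−1 gap open/extend. Significance uses a score-threshold
proxy, E = m·n·2^(−λ′S) with λ′ = 11·log₂10/30 ≈ 1.218, calibrated once
so a score-30 hit against a 1 Mb database lands at ~1e−5; it is a
documented stand-in for a full Karlin–Altschul treatment, adequate for
ranking and cutoff purposes. On small test databases the proxy is
conservative; callers there pass a relaxed `max_evalue_proxy`.

`fill_gap` alternates: recruit reads matching each flank tip, extend the
flank inward by per-column majority (ties keep the earlier-ranked base),
check whether the flanks now overlap by ≥ `min_overlap` (40) bp at
≥ `min_identity` (0.95). On closure the inserted sequence is exactly the
consensus between the original flank ends; flank sequence outside the
junction is never modified. Extension projects each matched read
ungapped past the flank tip; reads with indels in the anchor region
project slightly off-register and are out-voted by the majority — a
limitation only at indel-error rates well above the intended use
(accurate or low-error reads at ≥ 10× local coverage).

## Polishing

Mapping is exact-seed-and-verify: 31-mers at three read offsets (start,
middle, end — one sequencing error cannot kill all three) locate
candidate sites; each is verified by edit-distance alignment accepting
≤ `max_mismatch` (2) edits, counting substitutions and indels together.
This reads the "1–2 base error" allowance as an edit budget: pyrosequencing
drafts owe most errors to single-base homopolymer indels, so a mapper
verifying substitutions only would systematically miss the reads needed
to fix the dominant error class. Multi-mapping reads go to the
lowest-edit site; exact ties are dropped. Circular drafts are unrolled by
appending the first (max read length − 1) bases, which is the amount a
wrapping read can actually need; placements wrap modulo the draft length.

Consensus: per column, if depth ≥ `min_depth` (3) and the plurality call
(base or deletion) differs from the draft with vote fraction ≥
`min_fraction` (0.6), the draft is corrected; insertions are handled
identically on inter-column junctions, with every spanning read counted
in the denominator. Indels are left-normalized within homopolymer runs —
per read, the deletion vote is swapped with the run-start match vote —
so reads entering the run at different offsets vote on the same column.
Ambiguous columns are logged and left unchanged, never N-masked.
Quality scores are parsed and ignored: correction is a plain majority,
and polishing a polished draft is a fixed point on clean data.

## Genome statistics

Base composition excludes Ns from the denominator and prints percentages
rounded half-up to 2 decimals (the convention of genome reports).
GC windows wrap on circular sequences; defaults (window 500, step 200)
are display choices, not biology. N50 follows the standard definition.
Reference coverage marks positions under unique-21-mer anchor spans.

Quadripartite detection pairs positions x, y with x + y ≡ S: each shared
k-mer (k = 25) between the sequence and its reverse complement fixes one
anti-diagonal S, seeds collapse onto the diagonal of their repeat pair,
and the best seeds are extended exactly, base by base, in both
directions (modular arithmetic handles repeats wrapping the origin).
Extension stops at the first mismatch: chloroplast IRs are near-perfect
copies, and the exactness invariant IRb = revcomp(IRa) is checked on the
result. The longer single-copy segment is labeled LSC, and IRa is the
repeat copy that follows it on the circle. Detection requires
`min_ir` = 10 kb by default — half the lower end of the published IR
size range — so spurious short inverted repeats never partition a
genome. A mismatch-tolerant mode is deliberately absent from the default
path.

## Phylogeny

The 15 conserved mitochondrial protein-coding genes are extracted by
annotated coordinates (minus strand reverse-complemented; the longest
copy of a duplicated gene kept, with a warning). Per-gene multiple
alignment is center-star: the center is the sequence with the maximal
summed pairwise global-alignment score (+1/−1/−2, linear gaps; ties to
the lexicographically first taxon), and pairwise alignments to the
center merge under once-a-gap-always-a-gap. For genes at mitochondrial
conservation levels the center-star approximation is effectively exact;
it is deterministic and self-contained. Every column containing a gap is
then dropped — an automated, reproducible stand-in for manual alignment
curation — and blocks are concatenated over the shared taxon set (taxa
missing a gene are dropped with a warning; `pad_missing` pads with Ns
instead).

Distances default to p-distance (the proportion of differing sites);
a Jukes–Cantor option exists because the substitution model behind the
published trees of this kind is typically unstated. Trees are classic
Saitou–Nei neighbor joining, exact on additive matrices; negative branch
lengths are clamped to zero and flagged. Bootstrap support resamples
alignment columns with replacement, rebuilds the NJ tree per replicate,
and reports the percentage of replicates containing each internal
bipartition of the original tree; the replicate RNG is seeded
explicitly, and taxa are canonically sorted so input order is
irrelevant.

## The synthetic generator

`FixtureSpec` defaults define the study conditions: a 150 kb chloroplast
genome tiled as 85 kb LSC + 25 kb IRa + 15 kb SSC + IRb = revcomp(IRa);
a 400 kb mitochondrial genome carrying the 15 conserved protein-coding
genes, three rRNAs, two identical 5 kb dispersed repeat copies, and one
2 kb chloroplast-derived insertion bearing trnM/trnH/trnS; A+T fraction
0.545; depth bands nuclear 2×, mt 70×, cp 120× with 10% CV; reads of
360 bp whose dominant error is a single-base indel at homopolymer runs
of ≥ 3 (rate 0.005 per run), plus substitutions at 0.001 per base.
Polishing scenarios use 100 bp reads — the accurate-short-read platform
that stage models. Depth draws are truncated at ±1.5 σ so the bands
cannot cross the default thresholds: the generator's contract is that
default-threshold binning is exact on its output, and threshold failure
modes are exercised by narrowing the bands explicitly, not by tail luck.
Gene "sequences" are random DNA at the genes' coordinates — every
consumer here works from coordinates and sequence identity, not codon
structure.

Fragmentation cuts each circle at random points (default five), stores a
random ~30% of contigs reverse-complemented with correspondingly swapped
edge polarities, and emits depths and edges in shuffled file order. By
default the dispersed repeats stay internal to contigs, keeping the
default round trip exactly solvable; `collapse_spans` instead cuts at
repeat boundaries and emits the repeat once with summed depth —
the figure-eight graph that exercises multiplicity estimation and
master-circle search. IR boundary bases are adjusted (one base per
boundary at most) so the planted repeat pair is exactly maximal;
otherwise a chance complementary base adjacent to an IR would make the
true maximal repeat one base longer than the planted one.

All randomness flows from explicitly seeded per-fixture generators;
identical specs produce identical bytes.

**What the generator does not emulate** — and therefore what green tests
do not demonstrate about field data: nuclear genomes with organellar
insertions (NUMTs/NUPTs) at organellar-like depth; chimeric or
misassembled contigs; depth variation along a contig; repeat families
with more than two copies or near-identical (rather than identical)
copies; sequencing-quality gradients; and real gene sequences (so
annotation-free gene finding is untestable here, and deliberately out of
scope). The deposited-genome checks in the acceptance tests exist
precisely to pin a few statistics to real records; they need network
access to fetch them.

## Problem sizes in the shipped checks

The acceptance script and property suites run at desk scale, chosen to
exercise every code path with comfortable margins: 100–200 traversal
fixtures of 12 kb genomes in ≤ 8 contigs (small enough for exhaustive
closed-walk enumeration to serve as an oracle), 50 gaps of 100–500 bp on
a 30 kb genome at 20× coverage, one 100 kb polishing draft with 500
planted errors at 30×, 100 random additive matrices of up to 8 taxa, and
20 full-size (130–170 kb) quadripartite genomes. Rates reported by
`scripts/acceptance.py` are measured, not asserted.

## Known limitations

- Binning is univariate in depth; k-mer composition or mixture models
  are out of scope by design.
- The traversal reports edge-supported circularity only; it cannot
  confirm a circle the way junction PCR would.
- Repeats longer than a read with more than two collapsed copies may
  admit several depth-maximal closures; the deterministic tie-break
  picks one, and the alternatives surface only as unused edges.
- The gap-filler's ungapped read projection degrades at high indel
  rates in the *reads* (indels in the *draft* are the polisher's job).
- Center-star alignment is a 2-approximation in the worst case; for
  deeply diverged genes a dedicated aligner should replace it upstream,
  and the tree machinery will consume its blocks unchanged.
- `nj_tree` is O(n³)–O(n⁴) in taxa as implemented; intended for tens of
  taxa, not thousands.
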