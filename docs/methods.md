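# Methods

`plastarch` implements a comparative structural analysis of annotated
circular plastid genomes: quadripartite architecture typing, a
mismatch-tolerant repeat census, gene presence/loss classification,
gene-order rearrangement with the signed reversal distance, cross-genome
correlation statistics, and the model-comparison layer used in selection and
clock analyses.  Everything is exercisable end to end on synthetic plastomes
with planted ground truth; this note records the models, parameters,
numerical choices and limits.

## Coordinate model

Sequences are circular; all coordinates are 0-based half-open on the forward
strand, converted at I/O boundaries (GenBank is 1-based inclusive).  Feature
parts are stored in forward-strand adjacency order; a feature split across
the origin (only produced by rotation) wraps once, and writing a genome first
rotates it so no feature wraps — GenBank join-across-origin dialects are too
inconsistent to emit.  `normalize_frame` rotates (and if needed flips) a
genome so the anchor gene — psbA, falling back to rbcL, then rrn16 — starts
at position 0 on the plus strand; this makes block orientation signs
comparable across genomes and is idempotent.  Gene symbols are canonicalised
(case, tRNA anticodon styles, rRNA aliases) through a packaged table plus
pattern rules.

## Synthetic plastomes

The generator is the test substrate, not a sequence-evolution simulator.  A
template genome is LSC + IRb + SSC + IRa on a circle with IRa the exact
reverse complement of IRb.  Defaults mirror typical flowering-plant
plastomes: LSC 85 kb, SSC 17 kb, IR 25 kb per copy (152 kb total), GC 0.37,
and a packaged 113-gene panel (60 LSC protein-coding genes, 22 LSC tRNAs, 18
IR residents including the four rRNAs, 13 SSC genes; 12 genes carry introns;
rps12 is flagged trans-spliced and excluded from intron calls).  Coding genes
are random valid ORFs (ATG start, no internal stops); intergenic spacers are
random sequence whose composition is tuned region by region so realized GC
hits the target within ±0.1 percentage points — stop-codon avoidance makes
coding sequence run ~1.4 points GC-rich, so spacers end up AT-rich, as in
real plastomes.  The bases flanking each IR junction are pinned to
non-complementary values so exact IR copies cannot extend by chance into
single-copy flanks; planted boundaries are therefore recoverable to the base
pair.

Structural events operate on the annotated genome and a truth manifest in
one step, so every expectation is phrased in downstream-output terms:

- **inversion** — reverse-complements an interval, flipping and reversing the
  features inside; an interval cutting a feature part is rejected (or, on
  request, split with both fragments flagged pseudo).
- **ir_expand / ir_contract** — move an IR boundary by duplicating a donor
  stretch into the opposite junction (expansion: genome grows by the shift,
  absorbed genes gain an IR copy) or deleting the mirror of a retracted tail
  (contraction: genes in the tail fall back to single copy).
- **ir_loss** — deletes one whole IR copy; **insert_sir / insert_dr** then
  plant a short inverted (default 600 bp) or direct (default 1650 bp,
  matching the observed case) repeat pair in single-copy space.  The sIR
  default stays below the 1 kb IR-detection floor on purpose: an inverted
  remnant above that floor is indistinguishable from a (small) IR.
- **ir_triplicate** — inserts a prefix of IRa (default 8 kb, trimmed to a
  feature-free boundary) into the LSC, oriented like IRa.
- **insert_repeat** — plants a dispersed repeat pair of given length,
  orientation and identity in single-copy intergenic space.

Gene degradations: **delete** and the removed tail of **truncate** overwrite
the locus with GC-matched random sequence rather than shrinking the genome,
so region sizes and architecture stay fixed while no trace of the gene
remains; **premature_stop** substitutes a single in-frame stop codon (identity
elsewhere 100%); **intron_delete** excises the intron so the exons become
contiguous; **duplicate** copies the locus into a distant single-copy gap.
Manifest expectations follow the status rules below (truncation to a
fraction below 0.6 is expected lost, at or above it fragmented).

One seed drives three independent generator streams (template, events,
degradations); (config, seed) is byte-reproducible.  What the generator does
*not* emulate: substitution along a phylogeny, indels, codon-usage bias,
heteroplasmy mixtures.  Passing recovery tests therefore demonstrate
correctness of the detection logic under substitution/truncation-style
divergence, not performance on distant homology.

## Repeat census

Repeats come in forward, reverse (reversed, not complemented) and
palindromic (reverse complement) orientation.  A hit is a *maximal* pair:
extending one base on either side would exceed the Hamming budget or leave
the sequence.  Defaults follow plastome surveys: min 30 bp, max 5 kb, up to
3 mismatches; N never matches.  The finder seeds exact k-mers at the
pigeonhole length ⌊(min_len − max_mm)/(max_mm + 1)⌋ (a window of length L
with k mismatches has runs summing to L − k, hence a run of at least that
length), merges seeds into exact cores per diagonal, extends, and enumerates
the ≤ max_mm + 1 maximal windows around each core.  On sequences above 8 kb
the seed is raised to ≥ 12 bp for speed; the exhaustive guarantee then
applies to repeats containing a 12 bp exact run — every repeat of practical
interest, and all planted ones.  A reverse/palindromic window whose two
copies overlap is self-symmetric and is reported once as its two
non-overlapping arms (an 8 bp palindrome is a pair of 4 bp arms).  Circular
sequences are scanned on `seq + seq[:max_len]` with wrapped duplicates
removed.  The oracle (`brute_force_repeats`, ≤ 5 kb) scans **every**
diagonal with prefix sums and a per-start greedy right-maximal window — an
independent formulation the finder must match exactly, which the tests
assert on hundreds of seeded sequences.  Note that raising `max_mm` merges
neighbouring maximal windows, so hit *counts* are not monotone in the
budget; containment of every stricter hit in a relaxed hit is the monotone
property, and lowering `min_len` is count-monotone.

## Architecture typing

IR detection chains exact 21-mer seeds per diagonal of the genome against
its reverse complement (gaps up to 200 bp tolerated as substitutions), takes
the longest disjoint inverted pair of ≥ `min_ir` (default 1 kb) with copy
identity ≥ 98% (ties: identity, then smaller start), and extends block edges
by maximal exact identity — base-exact on exact copies.  A third copy (IRc,
oriented like IRa, allowed shorter, as observed) is admitted as a direct
match of either primary copy lying outside both.  With fewer than two large
copies, a remnant search over inverted pairs in [50 bp, min_ir) (sIR) and
direct pairs ≥ 50 bp with no upper cap (DR — a direct pair can never be
confused with an IR, and observed DRs exceed 1 kb) reports the longest
candidate.  Regions: the two inter-copy arcs are the single-copy regions,
larger = LSC; per-region GC excludes N.  With three copies the largest arc
is the LSC and the remaining single-copy space is reported as SSC (the
third copy genuinely splits one arc).  Class assignment: triple_IR (3
copies) > ir_loss_sIR / ir_loss_DR (remnant kind) > expanded (a canonical
single-copy gene lies wholly inside an IR copy) > contracted (a canonical IR
resident lies wholly in single-copy space) > canonical; canonical homes come
from the packaged panel.  The 1 kb IR floor is a judgement call exposed as a
flag: an inverted remnant of several kb (the observed 3.3 kb sIR) would
classify as a small IR under a lower floor.

## Gene inventory

Status is called from sequence, not annotation.  Each reference gene (exon
sequences + intron model, taken from an undisturbed template or any trusted
source) is located per exon by exact match or seeded 17-mer candidates on
both strands; each candidate is scored on its gap-free diagonal by the
maximal-scoring segment (match +1, mismatch −1 — exactly what an affine
local aligner returns when indels are absent, the regime of the degradation
model).  Exon hits cluster into loci; a locus qualifies at ≥ 60% pooled
identity over aligned columns and ≥ 60% reference coverage.  No qualifying
locus → **lost**.  A qualifying CDS locus whose in-frame translation carries
an internal stop, or whose coverage is below 95% (incomplete reading frame),
is **fragmented**.  Copies inside detected IR intervals are tallied
separately (`ir_copies`), so the canonical IR pair is *present*, not
duplicated; **duplicated** requires at least two loci outside the IR (or an
extra dispersed copy beside the IR pair).  Intron *i* is present when
consecutive exon hits sit ≥ 200 bp apart, absent when contiguous within
20 bp, undetermined otherwise; lost genes report undetermined introns
(never counted as intron loss), and trans-spliced genes return an explicit
unsupported marker.

Loss events are counted on a rooted tree by uniform-cost small parsimony
with the root fixed to *present* (panel genes are ancestrally present in the
plastome); among minimum-total-change reconstructions the minimum number of
presence→loss transitions is reported, computed by a lexicographic
(changes, losses) Sankoff pass — deterministic, and matched against
exhaustive enumeration of all ancestral labelings on trees of ≤ 8 tips.

## Rearrangement

Anchors are shared single-copy genes after masking the earlier-start IR copy
in each (normalized) genome — gene-order collinearity replaces sequence
alignment because inputs are annotated, making block construction
deterministic with no external aligner.  Maximal runs of anchors consecutive
in both genomes with consistent orientation collapse into locally collinear
blocks; blocks are relabelled 1..n in reference order, giving a signed
permutation (whitespace-separated signed integers on I/O).  Maximal runs of
negative blocks become inversion calls with query interval and gene content.

The reversal distance uses Hannenhalli–Pevzner theory on the capped
breakpoint graph: d = (n + 1) − c + h + f with c alternating cycles, h
hurdles and f = 1 for a fortress.  A gray edge is oriented when its two
endpoints share position parity; components are connected sets of
non-trivial cycles under gray-edge crossing; a hurdle is an unoriented
component whose positions are consecutive once only unoriented-component
positions are scanned; a superhurdle's removal would promote a non-hurdle,
and a fortress is an odd number of hurdles, all superhurdles.  The formula
is checked against a pure breadth-first search over the reversal graph for
**every** signed permutation with n ≤ 6 (46,080 at n = 6 — fortresses
already occur there), and against an exact iterative-deepening search pruned
only by the classical cycle bound d ≥ n + 1 − c at n = 7, 8.  Distances are
computed on linear permutations (the circle is cut at the normalization
anchor), matching how rearrangement distances are conventionally computed on
IR-reduced plastomes.

## Comparative statistics

The feature table carries the eight standard per-genome variables: GC
content, repeat number, genome length, LSC/SSC/IR length (IR = one copy;
remnants are never counted as IR), rearrangement distance, protein-coding
gene count (status present or duplicated).  Genomes missing a component are
flagged incomplete and excluded from correlations by default (a flag admits
them), mirroring the practice of restricting structural statistics to
complete assemblies.  Correlations are Pearson r with two-sided p from the t
distribution; |r| ≥ 0.8 is strong, 0.5 ≤ |r| < 0.8 moderate, < 0.5 weak.
P-values are reported raw — no multiple-testing correction is applied, a
deliberate and documented limitation.  Root-to-tip distances sum branch
lengths from the root (unrooted trees are refused), with per-group
mean/min/max summaries.

## Model-comparison layer

Likelihood optimisation of codon and clock models is out of scope; the
module consumes fit summaries.  LRT: 2(lnL₁ − lnL₀) against chi-square with
df = Δnp; a statistic negative beyond 1e−8 flags an upstream optimiser
failure and is clamped to zero.  AICc = −2 lnL + 2 np + 2 np(np+1)/(n − np − 1)
with n defaulting to the alignment column count (the choice is exposed — the
convention is not universal).  A gene is called positively selected iff
p < 0.05 and ω > 1; sites at posterior > 0.95.  The packaged published LRT
table (8 genes × 3 site-model comparisons) anchors the arithmetic: tests
recompute every printed p-value from its printed (2ΔL, df) to displayed
precision, with the tolerance widened by the uncertainty the rounded
statistic itself propagates; one row whose printed p is inconsistent with
its own printed statistic beyond rounding is flagged in the table and
compared loosely.

`ng_dnds` is Nei–Gojobori (1986) counting with Jukes–Cantor correction:
per-codon synonymous site fractions averaged over the two sequences,
pathway-averaged difference counts over all orderings of the differing
positions, dN = −(3/4)ln(1 − (4/3)pN) and likewise dS; ω is flagged
undefined at dS = 0.  Mutational steps through stop codons are excluded from
pathways (if every path is blocked, the constraint is dropped), and
mutations to stops never count as synonymous opportunity.  It is a
self-contained counting stand-in for ML codon-model rates, adequate for the
decision layer and synthetic tests, not a substitute for ML estimates on
saturated data (the JC correction fails above 75% raw divergence and raises).
Branch-rate summaries exclude branches with dN or dS below 0.001 — a
near-zero denominator makes ω arbitrarily large — and log the exclusions.

## Problem sizes used by the test and acceptance runs

Chosen so the full closed loop runs comfortably on one CPU: exhaustive
reversal-distance validation to n = 6 plus 200 exact-search cases at
n = 7–8; repeat-census oracle equivalence on 200 sequences of 0.1–2 kb;
54 architecture genomes (9 seeds × 6 classes, full 152 kb genomes);
108 degradations across 12 genomes; 200 random ≤ 8-tip trees for loss
parsimony; a 40-genome cohort for the repeat↔rearrangement positive
control.

## Known limitations

- Detection assumes the normalized frame; an IR spanning the sequence origin
  of an un-normalized linear dump is not chained across the seam.
- Flip-flop SSC orientation isomers and assembly-graph heteroplasmy are out
  of scope; one arbitrary isomer is analysed.
- The gene classifier's gap-free scoring will under-call identity for
  within-exon indels; real-data use at larger divergence should re-check
  borderline calls with a full local aligner.
- Hit counts of the repeat census depend on the maximality convention;
  other tools' counts (different seeding, merging of degenerate overlaps in
  low-complexity runs) are comparable only qualitatively.
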