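# Methods

## SSR detection model

The scanner reports perfect and imperfect tandem repeats of motif length 1–6.
A candidate begins at a *seed*: `min_seed_repeats` (default 3) exact copies of
a primitive motif. The seed is extended base by base in both directions
against the phase-anchored motif template; each position scores +1 on match
and −`mismatch_penalty` (default 5) on mismatch, and extension stops at an
`N`, at the sequence end, or when the running score falls
2 × `mismatch_penalty` below its running maximum (two unrecovered
mismatches). The locus is truncated to the best-scoring endpoints and kept if

    score = matches − mismatch_penalty × mismatches ≥ min_score (default 15).

With these defaults a perfect repeat must span ≥ 15 bp, and one substitution
must be paid for by six additional matching bases. Anchoring the template at
the seed (rather than comparing each base to the base one period earlier)
makes one substitution cost exactly one mismatch instead of propagating.

Motifs are reported canonically as the lexicographically smallest rotation of
the primitive period ("AAAA" is an (A)n locus, "CA" reports as "AC").
Reverse complements are *not* folded together — (TG)n and (CA)n are distinct
motifs — because upstream/downstream identity of a motif pair is part of the
object under study. Same-motif overlapping candidates are merged keeping the
higher score; identical intervals across motifs keep the higher score, then
the shorter motif. Overlapping loci of *different* motifs are both kept.

`N` handling is conservative: `N` never matches and immediately terminates
extension, so assembly gaps cannot bridge two repeats.

## Adjacent pairs and rMP families

Within each sequence, consecutive SSR loci form adjacent pairs; the
intervening distance *d* counts the bases strictly between them (abutting
loci have d = 0). Pairs whose loci overlap (possible for different motifs)
are skipped and logged. The ordered motif pair follows genomic left-to-right
orientation, matching the directional notation (TG)n–1022 bp–(CA)n.

Families group pairs by (ordered motif pair, distance). The default
tolerance is 0 — the conservative, exactly-equal-distance criterion. With
tolerance t > 0 the modal distance of a motif pair is taken first (ties:
smaller distance), everything within ±t is merged at the modal distance, and
the procedure repeats on the remainder. Greedy modal clustering is simple
and deterministic; when distance clusters are closer together than 2t a
larger cluster can annex members from a smaller one, so monotonicity of
family sizes in t is only guaranteed for well-separated clusters (the
regime the tolerance option is meant for, e.g. slippage-shifted spacers a
few bp apart).

## The association test

For a family (P, d): n = all adjacent pairs in the genome, n1 = pairs at
distance d, n2 = pairs with motif pair P, n3 = pairs with both. n1 and n2
include the overlap n3. The p-value is the upper hypergeometric tail
P(X ≥ n3) for X ~ Hypergeom(n, n1, n2), computed by `scipy`'s log-space
survival function (stable to n ≈ 10^6) and verified against an exact
integer-arithmetic tail sum. Bonferroni correction multiplies by the number
of families tested in the genome; significance threshold 0.05.

n is the realized pair count Σ(loci_i − 1) over sequences, which equals
"total SSRs minus one" only for single-sequence genomes.

The test conditions on (n1, n2) and is therefore a *per-family* measure of
surprise, not a family-discovery procedure with controlled genome-wide error:
when the distance distribution is diffuse (n1 of 2–4), any chance recurrence
looks extreme. This is inherent to the method and is why the shuffled-genome
control (below) uses compositionally biased sequence whose spontaneous SSR
spacings are concentrated.

## Shuffle-and-sample null

Each source sequence is character-shuffled independently (its base
composition is preserved exactly); 1000 fragments of 1 kb are then drawn
uniformly from the disjoint tiling of the shuffled sequences, without
replacement and never spanning sequence boundaries. Disjoint sampling
matters: overlapping samples of the same shuffled region would duplicate the
same locus pairs and fabricate exactly the repeated-pair signal the null is
supposed to lack (a pseudo-replication artifact that small synthetic sources
are prone to; genome-scale sources make overlap negligible either way).

## Segmental-duplication calling

Families with distance > 1 kb (strict) have their intervening sequences
extracted and aligned all-vs-all with a global affine aligner (match +1,
mismatch −1, gap open −2, gap extend −1; Biopython's `PairwiseAligner`).
Identity = matching columns / all alignment columns, gaps in the denominator
(the conservative choice; a matches/shorter-length variant is a parameter
away). Members with identity > 0.90 (strict) to at least one other member
qualify, via single-linkage components of size ≥ 2; one mSD family is
reported per rMP family, and the full identity matrix is exposed for
external tree building. Sequences above a 50 kb cap — which the distance
distribution of real rMPs does not reach — fall back to a banded
edit-distance alignment (edlib) scored from its extended CIGAR.

Whether published 90% thresholds refer to global or local alignment identity
is generally ambiguous; global is the default here and the scoring is
configurable.

## Genomic windows and co-aggregation

Chromosomes are tiled either by an explicit breakpoint list (the
per-chromosome megabase binning style: < 1 Mb, 1–5 Mb, …, > 50 Mb) or
uniformly (default 1 Mb; 50 kb in the synthetic co-aggregation study).
Family members are assigned to windows by pair midpoint, half-open on the
right. The co-aggregation statistic is the Spearman correlation between
per-window rMP and mSD member counts (two-tailed p), plus the squared
Pearson correlation of the linear fit; windows with zero rMPs are retained
by default since dropping them would bias the correlation upward.

## Annotation overlap

Features are held 0-based half-open; GFF3 input (gene records) is converted
from 1-based inclusive, BED passes through. A locus overlapping any gene by
≥ 1 bp is genic; otherwise a TE overlap makes it TE-associated; otherwise
intergenic. Gene-over-TE precedence gives a deterministic partition while
raw per-class overlap flags are emitted alongside. Nearly identical paralogs
are flagged when a paralog pair at ≥ 90% identity has both genes overlapping
members of the same mSD family.

## Synthetic genomes

The generator emulates only the statistical structure the analysis assumes:
i.i.d. background of chosen GC content, SSR arrays planted singly or as
motif pairs at fixed spacing, and > 1 kb duplications with SSR termini whose
copies carry i.i.d. substitutions at a chosen rate (no indels by default, so
expected identity to the master copy is exactly 1 − rate; substitutions
never resample the same base). Every insert carries 25 bp of random flank
and is re-drawn until the scanner reports exactly the intended loci at the
intended coordinates, so family truth tables are exact at tolerance 0.
Spontaneous repeats in the background are left in place for realism and are
excluded from truth assertions. Enrichment regions multiply local placement
density, creating the rMP/mSD-rich windows for the co-aggregation study.

Study scenarios (defaults chosen once, as the package's own desk-scale
conditions):

- **Demonstration / recovery**: 4 × 500 kb at GC 0.5; 20 rMP families
  (copies 2–8, distances 5–2500 bp) and 8 SD families (1.5–2.6 kb segments;
  five at substitution rate 0.05, three at 0.15, bracketing the 90% identity
  threshold).
- **Null calibration**: 20 seeds of 2 × 250 kb at GC 0.35 (AT-rich, as
  insect assemblies are) with nothing planted. I.i.d. background at this
  scale contains essentially no score-15 SSR, so the check degenerates to
  "no false families are invented"; the substantive null is the shuffle
  control.
- **Shuffle control**: a 1.5 Mb six-scaffold genome in which three scaffolds
  are ~90% mononucleotide arrays — the repeat-dominated scaffolds of draft
  assemblies — and three are ordinary background carrying ten planted
  families. Direct analysis flags essentially the planted families;
  after shuffling, fragments of the repeat-rich scaffolds still yield
  abundant spontaneous SSR pairs (the composition survives shuffling) whose
  spacings are random, and ≥ 90% of the resulting families test
  non-significant.
- **Co-aggregation**: one 1.2 Mb chromosome, 50 kb windows, a 200 kb region
  with 10× placement density; 30 rMP families and 12 SD families of two
  copies each. The window Spearman correlation is positive with p < 0.05 in
  every tested seed.

These sizes keep a full test-suite run in minutes on one CPU while leaving
every per-genome quantity (pair counts, family counts, tail probabilities)
far from degeneracy.

## What the synthetic tests do not show

The generator produces neither the slippage-generated length polymorphism of
real microsatellites, nor indel divergence between duplication copies, nor
transposon dynamics, nor assembly artifacts (collapsed repeats, chimeric
scaffolds). Passing recovery tests therefore demonstrates correctness of the
detection/grouping/testing machinery under the stated model, not robustness
to every property of real assemblies. Copy-number variation between the two
arrays of a pair shifts the intervening distance by whole motif lengths; the
tolerance parameter (±1–20 bp) is the instrument for that, and the default
tolerance 0 is deliberately conservative.

## Numerical and degenerate-input conventions

Coordinates are 1-based inclusive in SSR/pair tables, 0-based half-open in
BED and all interval arithmetic. Empty sequences scan to empty locus lists;
empty family lists raise on testing (there is no test to run) but summarize
as 0%. A family whose motif pair occurs only at its own distance has
n2 = n3. The hypergeometric tail returns exactly 1.0 for n3 = 0. Identity
of a sequence with itself is exactly 1.0. Window tilings always cover
[0, length) exactly; the final window absorbs remainders. All RNG flows
from `numpy.random.default_rng` seeds; fixed seed means byte-identical
genomes, truth tables and outputs.
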