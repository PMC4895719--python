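# Methods

This note documents the models, defaults and numerical choices behind
`subtracta`, and what the synthetic study does and does not establish.

## The comparative-subtraction model

The package formalises trait-gene discovery as set algebra over
homology searches. For a trait present in species A and absent in
species B, candidates are genes that are (i) present/expressed in A but
absent from B's genome or transcriptome under a homology threshold, and
(ii) responsive when the trait is experimentally re-induced in A. Both
conditions are computed independently and intersected
(`cross_subtract`), which makes the procedure robust to errors in
either branch: a false absence survives only if the same gene is also a
false positive of the expression screen.

Subtraction is deliberately asymmetric and conservative: a gene is
declared absent only after (1) a direct translated (six-frame) query of
its own sequence, (2) a rescue re-query using its reference best match
(protecting against assembly truncation of the query), and — in the
genome workflow — (3) searches against every available evidence layer
(assembly, resequencing reads' assembly, RNA-seq, ESTs, BAC ends).
Adding evidence can only shrink the absent list (anti-monotone), and
disabling rescue can only grow it; both properties are tested.

## Alignment and significance

The kernel is exact Smith–Waterman (Biopython's `PairwiseAligner`):
nucleotide +1/−2 with gap open −5 / extend −2; protein BLOSUM62 with
−11/−1. Significance is the Karlin–Altschul form
`E = K·m·n·e^{−λS}` with frozen constants (λ = 0.318, K = 0.13 for
BLOSUM62; λ = 1.28, K = 0.46 for nucleotide), where `n` is the total
database residue count of the run. These constants are a proxy, not a
fit: the contract throughout is *threshold equivalence* with the
heuristic search tools this replaces (cutoffs at 1e−5 / 1e−10), not
score equality. An optional shared-k-mer prefilter (k = 4 for protein,
11–12 for nucleotide) skips hopeless pairs; it only ever removes pairs
whose exact score would fall far below any threshold of interest.

## Clustering

Family clustering is single-linkage transitive closure over hits
passing identity ≥ 30% and overlap ≥ 50%, with overlap defined as
min(query coverage, subject coverage). Orthologue groups come from
Markov clustering: column-normalised random walk with per-node
self-loops (weight = the node's max incident weight), expansion 2,
inflation 1.5, entries < 1e−5 pruned and at most 200 kept per column,
converged when the matrix changes by < 1e−8 (hard cap 200 iterations;
non-convergence raises with the residual). MCL runs per connected
component, so clusters provably never span components; cluster output
order is lexicographic, making runs deterministic.

The duplicate-gene threshold ladder re-clusters each looser rung's
clusters internally at the stricter cutoff. This yields nested
refinements by construction — the property the cluster-count-versus-
stringency curve is meant to display — whereas independent MCL runs per
rung are not guaranteed nested.

## Ka/Ks

NG86 with equal-weight pathway averaging and Jukes–Cantor correction;
proportions ≥ 3/4 are reported as saturated rather than numbers.
Substitutions creating stop codons count as nonsynonymous in site
counts, and mutational orderings passing through a stop are excluded
(if every ordering does, all are used). NG86 replaces model-averaged
estimators on purpose: it is deterministic, closed-form and desk-scale.
Absolute Ks values can differ from model-averaged ones, but the
Ks < 1 recency classification is robust in the regimes simulated here.
Codon alignments are protein alignments back-threaded to nucleotides
with gapped codon columns dropped pairwise; gap placement is ambiguous
up to co-optimal shifts, which perturbs Ks only marginally.

## Differential expression

The design this emulates pools nine fish per time point into a single
library, so no replicate-based variance estimate exists. The default
test is therefore a two-proportion exact-style count test: conditional
on a gene's summed count across the two libraries, the focal count is
binomial with p = L_t/(L_t + L_0); the doubled smaller exact tail is
the p-value (vectorised through `scipy.stats.binom`; the test is
pluggable). Benjamini–Hochberg runs within each contrast, and the
study-level DE set is the union over time points — matching a design
that reports one DE list over the whole course. Fold changes are RPKM
ratios with pseudocount 1; calls require |fold| ≥ 2 *and* q < 0.05.

Limitation, stated plainly: with a single library per condition the
binomial test assumes at-most-Poisson sampling. Strong extra-Poisson
dispersion inflates its significance, and error control then rests on
the fold-change gate. The calibration simulations (dispersion 0.01,
see below) show the combined gate holding the null call fraction well
under the nominal 5%; at dispersion 0.1 the test retains full power
for 8-fold inductions but nominal FDR control should not be assumed
for real, highly dispersed designs without replicates.

## Synteny-anchored loss calling

Blocks are greedy chains of colinear orthologue anchors allowing up to
5 interleaved non-anchor genes per genome and one orientation per
chain (≥ 2 anchors per block). Any colinearity detector with these
semantics would do; greedy chaining is chosen for determinism. A query
gene is evaluated by aligning each coding exon against the B-genome
interval between its flanking anchors (both strands, per-exon
E ≤ 1e−5): coverage ≥ 0.8 of coding length ⇒ present, in (0.1, 0.8) ⇒
remnant with a per-exon hit map, ≤ 0.1 ⇒ absent. The floors are
declared stand-ins chosen so that a locus retaining a minority of its
exons maps to "remnant" and a full deletion to "absent"; both are
configurable. Promoter scans are IUPAC-degenerate exact matches on
both strands in a 2-kb upstream window.

## The synthetic study

`synthgen` emulates the comparative setting with a content-free
sequence null: ancestral genes are uniform random codons (table 1),
60–150 codons in 6 exons, placed in order on 2 chromosomes (2 scaffolds
each) with random spacers, introns and a planted 12-bp promoter motif.
Orthologs diverge by synonymous-only substitutions (default Ks 0.2), so
protein-level homology is unambiguous while nucleotide identity decays
realistically. Losses are full (locus deleted) or remnant (exactly one
exon — the fifth — survives, promoter lost). `mutate_to_ks` steers
synonymous divergence to a target NG86 Ks within ±15% (analytic
Jukes–Cantor warm start, then stepwise refinement), or flags
saturation.

The expression course has 8 time points (0 h–21 d) with induction from
day 5 onward, matching the observed timing of scale regeneration.
Counts are gamma-Poisson (variance μ + d·μ²) with expected values
proportional to gene length × baseline × induction. Defaults are the
study conditions: 50 ancestral genes, 5 full + 5 remnant losses in the
scaleless lineage, the 5 fully lost genes induced 8-fold, library size
1e6. Dispersion defaults to 0.01: pooling nine individuals shrinks a
typical ~30% per-individual biological CV to ~10%, and d ≈ CV². Induced
genes carry a 0.02× baseline before induction — regeneration genes are
near-silent in resting skin — which also keeps the 50-gene panel's
library composition stable under induction (with only tens of modeled
genes, a large induced baseline would shift RPKM of every null gene,
an artefact of small panels rather than of real transcriptomes).

What passing tests show: the pipeline's set algebra, thresholds,
statistics and remnant logic are correct on data whose truth is known,
across seeds. What they do not show: performance under annotation
error, assembly fragmentation, paralogue interference beyond the
planted cases, or overdispersed unreplicated designs — the synthetic
null is content-free and the divergence model synonymous-only.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally, 1-based inclusive in
  GFF3; strand '.' is accepted and both strands are always scanned.
* Tandem gap is end-of-upstream to start-of-downstream, inclusive at
  10,000 bp; overlapping genes count as gap 0.
* Window counts use half-open bins [k·w, (k+1)·w); hotspot ties break
  to the lowest coordinate.
* Map-concordance flags a breakpoint for oriented backward cM steps
  > 0.5 cM (tolerance for map jitter); scaffolds touching two linkage
  groups are chimeric regardless.
* All-zero genes get p = 1 and defined fold changes (never NaN);
  zero library sizes are errors.
* Unreachable Ks targets return a saturation flag, not an exception.
* All randomness flows through one seeded numpy generator per run; the
  seed is recorded in the planted truth, and emitted artefacts hash
  identically across reruns.

## Problem sizes

Defaults are desk-scale by design: 50-gene scenarios for end-to-end
recovery, 2,000 genes × 20 replicates for null calibration, 300-codon
pairs for estimator checks, 500 random instances for the clustering
oracles. All are package choices tuned to keep a full validation run
in minutes on one CPU while leaving every statistical conclusion
Monte-Carlo stable across seeds.
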