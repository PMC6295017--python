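# Methods

## The synthetic collection and what it does (not) emulate

`forge.evolve_collection` simulates a strain collection descending from a
single ancestor. The ancestor (default 100 kb) is tiled by `n_blocks`
(default 40) homologous blocks whose lengths are drawn from
`block_length_range` (default 1200–5000 bp) and adjusted within those
bounds to sum exactly to the genome length; a configuration whose range
cannot tile the genome is rejected. Each descendant genome then

1. applies `n_rearrangements` random moves to the block order — an
   inversion (reverse a contiguous run and flip orientations) or a
   translocation (move a contiguous run elsewhere), chosen with equal
   probability. Moves act on whole blocks only, so the planted block map
   is the exact collinear-block truth;
2. substitutes each site independently with probability
   `substitution_rate` (default 0.02), always to a different base. There
   are no indels, so ancestral coordinates align exactly between genomes
   and pairwise identity has a closed form: two lineages at rate r
   disagree at a site with probability 2r(1−r) + (2/3)r². The generator
   stores the realized mismatch fraction per pair as the ANI oracle.

Gene content is simulated separately from the nucleotide sequence: a core
set present in every genome (default 200 families), two planted
genomogroups (default 5+5 genomes) with group-exclusive families of
deliberately unequal size (default 8 vs 3), and an accessory pool (default
100 families). Accessory families are **group-biased**: each has a home
group where carriage is common (probability 0.9) and is only sporadically
found outside it (0.05). This mirrors how gene-content clusters arise in
real species — accessory genes are gained and lost along lineages, so
genomes of one genomogroup share accessory content broadly rather than
differing only in a handful of exclusive markers. It is also what gives
the differential stage realistic operating conditions: with two groups of
five, the smallest achievable exact rank-sum p is 2/252 ≈ 0.008, so a
matrix in which *only* the 11 exclusive families carry signal can never
yield q < 0.05 after Benjamini–Hochberg correction across ~300 groups;
group-structured accessory content is the regime in which the planted
families are recoverable at all.

Proteins are random 20-letter sequences shared within a family (length
80–200 aa) with per-genome substitutions at rate 0.05 — similar enough for
unambiguous recovery, divergent enough that recovery is not trivial.
Optionally, `paralog_families` core families receive a second copy in one
random genome, making the strict single-copy marker set a proper subset of
the core.

Each genome draws from its own RNG stream
(`SeedSequence(seed, spawn_key=(1, i))`), so enlarging a collection never
perturbs existing genomes, and identical configurations are byte-identical.

What the generator does **not** emulate: indels and unequal genome sizes
(block coordinates would no longer be exact), codon structure and
selection, HGT from outside the collection, mobile-element sequences, and
assembly artifacts. Passing tests therefore demonstrate correctness of the
*computations* on cleanly planted signal, not robustness to the alignment
ambiguity and annotation noise of real drafts — real-data runs go through
the external-tool adapters (BLASTN/BLASTP tabular, Mauve backbone), which
carry those burdens.

## ANIb

Fragment length 1020 bp and the 30%-identity / 70%-coverage fragment
filter are the standard ANIb choices. The trailing short fragment is kept;
for concatenated multi-contig drafts, fragments spanning a recorded contig
boundary are dropped. The built-in aligner seeds exact 16-mers (stride 8,
at most 4 subject positions per seed) on both strands, and on each
candidate diagonal takes the maximal-scoring ungapped segment (match +1,
mismatch −2; Kadane scan). On indel-free input this is exact; end-trimming
of mismatching bases inflates identity by well under 0.1 percentage point
at the divergences tested. Self-comparison yields ANI = 100 exactly.
"Reciprocal" ANI is reported as both directed values; summaries take the
median over directed off-diagonal entries by default and also report the
median of direction-averaged pairs, since conventions differ. Missing
pairs propagate as missing (NaN), never as zero. Species-level components
require *both* directions of a pair to reach the cutoff (default 95%).

## Synteny score

The score of an ordered pair (g0, g1) filters shared blocks to length
strictly greater than `min_block` (default 1000 bp) **in g0**, orders them
along g0 and ranks them by absolute start in g1. Block k ≥ 2 is syntenic
iff |iₖ − iₖ₋₁| = 1. Two edge conventions are deliberate: block 1 is
syntenic iff it is adjacent to block 2, and a single surviving block
counts as syntenic — any other reading makes two identical genomes score
below 100%, which would be absurd for a statistic whose comparison species
score 76–83%. Orientation is ignored for adjacency (the rule is about
order, not strand). The score is asymmetric (denominator L₀); matrices
keep both directions and the summary reports mean, sd **and** sem over
ordered pairs, labelled, since "±" conventions vary. Tied g1 start
coordinates cannot occur in valid backbone files; if encountered, ties
break by end coordinate with a logged warning.

`find_collinear_blocks` is a fallback for alignment-free input only:
unique exact matches of `min_anchor` bp (both strands) are chained on
common diagonals, merging chains separated by at most `max_gap` bp. It
assumes substitution-only divergence. Recovered boundaries may differ from
planted ones by a few bases when a junction k-mer coincidentally matches
across a block boundary (probability ~1/4 per preserved junction), so
truth comparisons allow anchor-length slack; `SyntheticTruth.pair_lcbs`
projects the planted map onto a pair and merges runs that are contiguous
and collinear in both genomes, which no alignment-based finder can split.

## Ortholog graph and MCL

Directed hits at E ≤ 10⁻⁵ become undirected edges when reciprocal; edge
weight is the mean of the two directed −log₁₀ E values, capped at 200
(E = 0 maps to the cap). Intra-genome (paralog) edges are kept when both
ends also have inter-genome reciprocal partners, or when the pair is
mutually better than each end's best inter-genome hit (recent paralogs) —
including the case of a duplicated family with no orthologs elsewhere.
Instead of OrthoMCL's full inter-species weight rescaling, weights are
normalized by the incident nodes' average edge weight; this is a
deliberate simplification, adequate because downstream conclusions rest on
presence/absence structure rather than exact cluster boundaries.

MCL iterates expansion (matrix square) and inflation (entrywise power 1.5,
column renormalization) on the column-stochastic adjacency with unit
self-loops, pruning entries below 10⁻⁵, until the maximum entry change
falls below 10⁻⁶ (at most 100 iterations; non-convergence returns the
current interpretation with a warning). Clusters are connected components
of the limit matrix; the procedure involves no randomness and is invariant
to node input order (nodes are sorted internally). Isolated proteins come
out as singleton groups.

Core groups have ≥ 1 copy in every genome; the strict single-copy set
(exactly 1 everywhere) doubles as the phylogenetic marker set. Because
paralogs make "core size" ambiguous, the partition reports both the group
counts and per-genome member-gene counts. Accumulation curves use 100
random genome orderings by default; when the collection is small enough
that n! does not exceed the requested permutation count, all orderings are
enumerated exactly once, making the curve exact rather than sampled.

## Genomogroup statistics

Ordination is PCA on genome profiles of orthogroup copy counts,
column-centred and unscaled — identical to PCoA with Euclidean distances
on these data. The gap statistic follows Tibshirani: within-cluster
dispersion W(k) from Ward.D2 clustering, references sampled uniformly in
the principal-axis-aligned bounding box (B = 50), optimal k the smallest
with gap(k) ≥ gap(k+1) − se(k+1); degenerate inputs with zero dispersion
return k = 1. Group assignment cuts the Ward.D2/Euclidean dendrogram;
labels are Roman numerals in decreasing group-size order, computed on a
canonical genome ordering so the assignment is input-order invariant.

Differential testing uses two-sided Wilcoxon rank-sum on copy counts
(presence/absence available as an option). For combined n ≤ 20 the exact
tie-aware null is enumerated over all C(n, n₁) labelings (two-sided tail
by distance of the rank sum from its mean); larger samples use the tie-
and continuity-corrected normal approximation. Constant orthogroups get
p = 1. Adjustment is Benjamini–Hochberg. COG enrichment compares, per
genome, the fraction of its COG-annotated core gene copies in each
category against the accessory fraction, with a paired two-sided signed-
rank test across genomes (a pooled rank-sum mode is available, since the
proper unit of replication is debatable) and Bonferroni correction over
the categories actually tested; groups with several category letters count
once per letter, and empty categories are skipped with a warning.

## Problem sizes and determinism

Tests and the acceptance script run on 100-kb genomes, 6–10-genome
collections, ~300 orthogroups, 20 replicate seeds for trend assertions and
50 label permutations for FDR checks — sizes at which every oracle
(exhaustive permutation enumeration, dense-matrix MCL, Lance–Williams
agglomeration, direct mismatch counting) is itself cheap to compute. All
randomness flows from explicit seeds; writers emit fixed column order and
6-significant-digit floats, and every pipeline output carries the tool
version, a hash of the analytic parameters, and the seed, so reruns diff
clean.

## Known limitations

The built-in nucleotide and protein aligners are not general-purpose: they
assume substitution-only divergence and will under-align indel-rich real
genomes, where the BLAST adapters should be used instead. The synteny
fallback cannot resolve repeats (anchors must be unique). MCL on very
large hit graphs would benefit from sparse blockwise scheduling that is
not implemented. The exact rank-sum path enumerates up to C(20,10) ≈ 1.8 ×
10⁵ labelings per orthogroup, which is fast at these scales but quadratic
pressure for matrices with tens of thousands of groups.
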