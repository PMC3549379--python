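# Methods

## Model

One binding site of fixed length L is assumed to occur in each of k
homologous promoter sequences (one-occurrence-per-sequence semantics; no
mixture model, no multiple occurrences, forward strand only). Candidate
sites are all length-L windows of each sequence; a prediction selects one
window per sequence maximising the summed pairwise similarity, subject to
every pair being individually significant.

Similarity is the ungapped position-wise sum of a symmetric 4×4 integer
log-odds matrix (identities 91–100; transitions −28; transversions −109 to
−140). The "alignment" of two windows is deliberately read as this
*ungapped* sum: the windows have identical length by construction and the
matrix defines no gap penalties, so a gapped aligner would be unsupported
by the scoring model and would silently shift every calibrated threshold.
This is the single most consequential interpretation in the package. The
matrix is user-replaceable (4×4 TSV with an `A C G T` header) for
experimentation; the packaged default is used everywhere else.

## Threshold calibration

Edges require a score at least c, where c is the smallest value whose
upper-tail frequency among M Monte-Carlo scores of random window pairs is
≤ p. The null pairs are i.i.d. per position with letter probabilities equal
to the pooled base composition of the input set — intentionally simple (no
dinucleotide or Markov structure), matching the i.i.d. background of the
synthetic generator so calibration on simulated data is honest. The rule is
purely empirical and distribution-free; a normal-quantile variant
(`gaussian=True`) exists for comparison only, since the score sum is
approximately normal at moderate L but the empirical quantile needs no such
assumption.

Numerical conventions:

* The tail is a step function that changes only at achieved score values,
  so the minimal integer c is always an achieved score; minimality and
  validity (tail ≤ p) are asserted on every calibration.
* Defaults: p = 0.001, M = 100 000. M = 1e5 stabilises the p-quantile to
  O(10⁻³) and runs in milliseconds vectorised; p is an artifact choice —
  see Limitations, because downstream sensitivity depends strongly on it.
* Edge rule is score ≥ c. Since c is minimal with tail ≤ p, on the integer
  lattice `≥ c` and `> c − 1` coincide.

## Clique search

Windows of sequence i form column i of a k-partite graph; edges never join
windows of the same column. Every start offset 0 … N − L is enumerated
(N − L + 1 windows), so a site ending on the final base is representable.

Pruning iterates to a fixpoint, removing vertices that cannot be in any
k-clique. The default rule removes a vertex lacking at least one neighbour
in *every* other column; the alternative `degree` rule removes vertices of
degree < k − 1. The per-column rule is strictly stronger and both are
sound, because a k-clique member has one neighbour in each other column and
hence degree ≥ k − 1. (A literal degree-< k cutoff would wrongly delete
clique members of degree exactly k − 1, so it is not offered.) Pruning is
invariant on the k-clique set — tested exhaustively at small scale.

Enumeration is exact and column-ordered: the working set starts as all
edges between columns 1 and 2, each further column extends each partial
clique by every vertex adjacent to all members, and partial cliques that
fail to extend are dropped after each column. Adjacency lives in per-vertex
bitmasks, so "is u adjacent to the whole clique" is one AND. The working
set is capped (default 5 000 000 partial cliques); a breach raises an error
advising a smaller p, since density — and hence the O(kWᵏ) enumeration —
is governed by the threshold. Among equal-weight maximum cliques the one
with the lexicographically smallest start-offset vector (in column order)
wins, making results deterministic; runs with identical inputs, p, M and
seed are byte-identical. The reported clique weight is recomputed
independently from the reported windows at output time.

An emptied column or an extinguished working set yields a `not-found`
status (exit 0 from the CLI) naming the first limiting column. Because
pruning cascades, the named column is the first to empty, which may differ
from the column that caused the cascade.

## Developer score

d = max(1 − D/L, 0) with D = |predicted start − true start| and L the
*true* site length, at full precision internally and rounded half-up to two
decimals only in reports. Predictions of a different length than L (some
baseline tools report 13-mers against 11-nt sites) still score by the
start-offset deviation with L the true length — the only reading that
reproduces the published 0.73 cells. When re-scoring predictions printed as
strings inside a flanked context, the true site is the capitalized run, the
prediction is located case-insensitively at its first forward-strand
occurrence, and predictions absent from the forward strand (including
literal "Not Found") score 0.0.

The packaged 67-row benchmark reproduces every published clique-method cell
exactly and the baseline (Gibbs sampler) cells in all but four rows whose
printed values are internally inconsistent with their own printed strings:
one reverse-complement call printed as a hit, two rows whose printed
prediction does not occur in the printed context, and one forward-strand
occurrence printed as a miss. Those four are documented and excluded from
cell-level comparisons.

## Synthetic data

The generator emulates the shapes of the real evaluation sets (20–27
sequences of 11–23 nt, one site of 6 or 11 nt per sequence): i.i.d.
background letters (uniform by default, any composition accepted), one
consensus occurrence per sequence at a uniform admissible start, each motif
position independently substituted to a uniformly chosen *different* letter
with probability m. Substitution-only mutation is deliberate — the detector
scores fixed-length ungapped windows, so indels would test nothing the
model represents. What passing synthetic tests do **not** show: real
promoters have correlated (non-i.i.d.) backgrounds, repeat structure, and
sites whose inter-sequence divergence is position-dependent rather than
i.i.d.; calibration against such backgrounds is anti-conservative.

## Limitations

* **Threshold sensitivity at realistic divergence.** With k = 20 sequences
  and an 11-nt site mutated at 5 % per position, p = 0.001 yields c ≈ 490
  (uniform-ish composition), while a pair of occurrences carrying 1 and 2
  substitutions at disjoint positions scores ≈ 385. About 10 % of
  occurrences carry ≥ 2 substitutions, so the probability that all
  k(k−1)/2 true pairs clear c is only ≈ 0.2 — and when any true edge is
  missing, typically *no* k-clique exists and the method reports
  not-found. Raising p helps only up to a point (even with no threshold at
  all, ≈ 6 % of such replicates contain a true pair scoring below any
  useful cutoff) and quickly densifies the graph toward the enumeration
  cap. The method is therefore best suited to strongly conserved sites, or
  to small p only when divergence is low; published sites differing at 4–5
  of 11 positions imply the original experiments ran at a far more
  permissive confidence level than 0.001.
* One site per sequence; a sequence genuinely lacking the site forces
  either a spurious assignment or a global not-found.
* Forward strand only; reverse-complement occurrences are invisible by
  design.
* Exhaustive enumeration is exponential in k in the worst case; the
  pruning stage and the cap make typical runs fast but give no worst-case
  guarantee.

## Problem sizes used in the test suite

Oracle-equivalence checks run on 200 random instances with ≤ 4 columns and
≤ 6 vertices per column against brute-force maximisation over all
selections. Synthetic recovery runs 20 replicates at the full stated shape
(k = 20, N ∈ [19, 23], L = 11, m = 0.05, M = 100 000, p = 0.001); the
threshold-sensitivity limitation above is measured by exactly this
experiment. Null-calibration checks use M between 2×10⁴ and 10⁵.
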