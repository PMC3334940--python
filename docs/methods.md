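# Methods

## Data model and binary encoding

Genotypes are dosage-coded integers (0 = homozygous major MM, 1 =
heterozygous Mm, 2 = homozygous minor mm) with `NA` for missing calls.
Each SNP expands into three boolean item columns in the fixed order
(mm, Mm, MM); a sample sets exactly one bit per SNP when the call is
non-missing, so a complete matrix has a 1-bit density of exactly 1/3.  The
transformation is lossless: decoding recovers the genotype matrix on all
non-missing entries.  A missing call leaves all three bits 0, which makes
any pattern touching that SNP *absent* in that sample — the conservative
choice for support counting.  Items are totally ordered by (SNP file
order, then mm < Mm < MM); this order fixes candidate generation and makes
all outputs deterministic.

Quality control drops SNPs with *strictly more than* `max_missing_frac`
missing calls (default 0.05: a SNP missing exactly 5/100 calls survives)
and, optionally, non-autosomal SNPs (X/Y/MT, any `chr` prefix).

## Pattern statistics

A pattern is a conjunction of genotype items at distinct SNPs; its
presence vs the phenotype forms a 2×2 table, so every pattern is tested
with Pearson's χ² at 1 degree of freedom regardless of its size.  This
fixed df is what makes χ² values of different sizes comparable and the
jump statistic meaningful.  Numerical conventions:

* no Yates continuity correction (statistics stay comparable across the
  large values this analysis produces);
* degenerate tables (a zero row or column margin) return (χ² = 0, p = 1)
  rather than NaN — such patterns carry no contrast;
* odds ratios apply the Haldane–Anscombe +0.5 correction when any cell is
  zero, and the correction is flagged in the output;
* the Fisher exact test is two-sided (conservative default); the batched
  implementation groups tables by the pattern-present margin and sums
  hypergeometric mass ≤ the observed probability (with the customary
  1 + 1e-7 slack against floating-point ties), and is cross-checked in the
  tests against both an independent enumeration oracle and the
  single-table reference routine;
* `jump(P) = χ²(P) − max over all 2^k − 2 proper subsets` includes size-1
  subsets in the maximum.  The reference implementation enumerates subsets
  exhaustively; the miner computes the identical quantity from its
  survivor tables (every size ≥ 2 subset of a survivor is itself a
  survivor, by anti-monotonicity) and the two are asserted equal in tests.

`SupMaxPair(P)` is the support of `P` in the enriched class minus the
maximum support among its size-2 subsets in the other class; for size-2
patterns the pattern is its own only size-2 subset.  Both enrichment
directions are mined in two symmetric passes; for any threshold > 0 the
directions are disjoint, so results are concatenated with a direction tag.

## Apriori search

Level-wise search with standard prefix joins under the global item order.
Level 1 keeps items whose support in the enriched class meets the
threshold (necessary for any qualifying superset, since the subtracted
pair maximum is non-negative).  Level 2 evaluates all item pairs densely
via co-occurrence matrix products.  From level 3 on, candidates join two
survivors sharing their first k−2 items; each surviving pattern carries a
packed 64-bit presence bitset per class, the child's bitset is the AND of
its parents', and counts come from hardware popcount.  The maximum size-2
subset support in the contrast class is maintained incrementally — for
P = prefix ∪ {x, y} every size-2 subset lies in parent 1, parent 2 or is
the new pair {x, y} — so no candidate ever rescans the sample matrix.

All threshold comparisons use a single shared predicate with a 1e-9 slack,
so float rounding cannot break the subset/superset ordering the pruning
relies on; the brute-force oracle uses the same predicate, which makes the
equivalence tests exact.  The classical all-subsets-survive check is
applied after the vectorised SupMaxPair evaluation rather than before it
(counting via popcount is cheaper than hashing here); anti-monotonicity
guarantees it never removes anything, and it is kept as a verification.

The candidate budget (default 5×10⁶) bounds the *surviving frontier* per
level; exceeding it aborts with an error advising a higher threshold.
Generated candidates are streamed per prefix group and never fully
materialised.  Gene-set constraints are packed per item into bitmasks over
retained gene sets; a candidate's mask is the AND of its items' masks and
must be non-zero — an anti-monotone prune applied at every level, with
unmapped SNPs failing at level 1.

`brute_force_mine` (≤ 20 SNPs) enumerates every SNP subset and genotype
assignment directly, with no pruning and no shared machinery; it is the
independence oracle for the search.

## Permutation FDR

Each permutation draws a uniformly random relabelling with the case count
preserved and reruns the complete configured pipeline — threshold, maximum
size, gene-set constraints and jump filter included — which is enforced by
a configuration digest.  χ² statistics of null patterns are pooled within
each size; `FDR = n / (N_perm · m)` with both counts taken as ≥ (the
pattern counts itself, so m ≥ 1 and the estimator is well defined; a
strictly-greater reading would leave the top pattern's m at 0).  When
n = 0 the FDR is 0 with upper bound `1/(N_perm · m)`.  Per-permutation
seeds are spawned from the master seed by index.  Defaults: 100
permutations for routine runs, 500 for the saturation experiment.  No
second-stage correction across sizes is applied; size-stratified FDRs
answer "how unusual is this pattern among patterns of its own size", and
users comparing across sizes should keep that caveat in mind.

## Synthetic data

Background: independent SNPs under Hardy–Weinberg equilibrium with MAF ~
Uniform(0.05, 0.5), identical in cases and controls.  This deliberately
replaces haplotype-based simulation: the properties exercised here (pattern
frequencies, support contrasts, FDR behaviour) depend on pattern presence
fractions, not LD structure.  Consequently the generator does *not*
reproduce linkage disequilibrium, population structure or allele-frequency
spectra of real cohorts, and passing tests say nothing about robustness to
LD-induced redundancy among patterns.

Embedding overwrites the pattern's genotypes into round-half-up(f·n)
randomly chosen samples per group and perturbs one pattern SNP in every
remaining accidental full match, so realized per-group presence counts are
exact while per-SNP marginals move as little as possible (perturbation,
not resampling).  Embedded patterns occupy disjoint SNPs.

Default design (four patterns, sizes 3–6): (f_case, f_ctrl) = (0.42, 0.05),
(0.40, 0.05), (0.35, 0.05), (0.30, 0.05).  With round-half-up at 70+70
these give overall frequencies 0.236, 0.229, 0.207, 0.179 — all below
0.25, the regime in which naive frequent-itemset mining at a practical
support threshold cannot see the patterns but SupMaxPair search can.  All
embedded items are minor-homozygote genotypes at SNPs whose MAF is forced
into [0.10, 0.35] (background item frequency 0.01–0.12): the binding
quantity for recovery is the maximum size-2 subset support in controls,
which is the exact embedded fraction (≈ 0.057) plus background
co-occurrence (≤ ~0.015 in expectation), leaving every pattern's realized
SupMaxPair above 0.15 with a wide margin for any seed.  Heterozygote items
at unconstrained MAFs can push pair co-occurrence above f_case − 0.15 and
mask the embedding, which is why the design pins the item genotype and MAF
range.  Sample-size presets (140 … 5600 total) share the embedded design
per seed, scaling counts at fixed per-group frequencies.

## Functional coherence

Patterns are grouped by jump at configurable bounds (default ±5).  Each
group contributes the union of its within-pattern gene pairs (same-gene
pairs dropped, unmapped SNPs skipped with a warning).  Similarity comes
from a user-supplied weighted gene-pair network, binarized at a cutoff
(default 0.5) for the "fraction functionally linked" summary.  The null
preserves each gene's occurrence count by double-edge swaps on the pair
graph (default 100 replicates, ~10 accepted swaps per pair); a pair set
with fewer than two pairs is its own only degree-preserving configuration.
Group-vs-group and group-vs-null comparisons use two-sided rank-sum tests
(normal approximation with tie correction); groups with fewer than two
pairs are excluded with a notice.  Pair sets are iterated in sorted order
throughout so results do not depend on hash randomisation.

## Problem sizes used in the test suite

The shipped experiments are sized for a single CPU: the reference mining
experiment uses the full 2172-SNP design at 70+70 samples; the FDR
saturation experiment uses a 300-SNP replica at 140+140 samples with 500
permutations; noise calibration uses twenty 150-SNP null datasets with 40
permutations each; oracle equivalence uses fifty instances of 6–15 SNPs.
These choices trade nothing qualitative away: every claim they check is a
property of the method at the stated sample sizes, not of the SNP count.

## Known limitations

* Jump filtering is post hoc by design (jump is not anti-monotone); a
  pattern whose every subset is weak but which jumps only above size 2 is
  found, but one below the SMP threshold is not.
* The FDR estimator is empirical; with few permutations its resolution is
  1/(N_perm·m).
* The generator's independence assumptions (no LD) understate the pattern
  redundancy seen in real genotype data, where many overlapping patterns
  can share a causal signal.
* Patterns with identical presence vectors are all reported; no
  redundancy-aware deduplication is attempted.
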