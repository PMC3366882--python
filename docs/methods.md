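# Methods

This note documents the statistical procedure genetrait implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was genuinely open.

## The association model

The data are a binary (or binarized) feature matrix X ∈ {0,1}^(n×p) over n
strains and p genes, and per-experiment categorical phenotype labels y.
Panels are small-n/large-p (tens of strains, thousands of genes), noisy
(wrong gene calls, ambiguous phenotypes), internally correlated
(co-inherited operons), and class-imbalanced. The pipeline treats each
phenotype experiment independently as a classification problem and asks, per
gene and per strain, whether the gene helps classify that strain correctly.

### Usability of an experiment

An experiment enters the analysis only if, after optionally removing
ambiguous-label strains (default ambiguous set: {"Maybe"}; removal on by
default, per experiment, configurable off), at least two classes each retain
k ≥ `k_min_class` (default 4) strains. The minimum analysable design is
therefore 2 classes × 4 strains = 8 strains. Classes below k in an otherwise
usable experiment are excluded from that experiment's samples.

### Preprocessing

* **Imputation** (`impute_missing`). Default is proximity-weighted
  iterative imputation: grow a bootstrap forest on the current fill, compute
  sample proximities (fraction of trees placing two strains in the same
  leaf), and replace each missing cell with the proximity-weighted average
  (continuous) or proximity-weighted majority (binary) of the feature's
  observed values; iterate up to 5 times. Requires labels; without them a
  mode/median fill is used. A feature with no observed values is an error.
* **Variance filter** (`remove_homogeneous`). Population variance
  (p(1−p) for a binary feature) below `variance_min` = 0.05 removes the
  feature. Over 42 strains this removes exactly the features whose minority
  value occurs in ≤ 2 strains (2/42 → 0.0454 < 0.05 < 0.0663 ← 3/42); the
  population (ddof=0) convention is chosen because it reproduces this
  boundary with the simpler formula — the sample convention would too, with
  a shifted constant.
* **Correlation collapsing** (`collapse_correlated`). Absolute Pearson
  ≥ 0.98 or absolute Spearman ≥ 0.95 marks two features as split-equivalent
  for trees (anti-correlated duplicates induce the same splits, hence the
  absolute values). Grouping is greedy in input feature order: the first
  unclaimed feature becomes a representative, and every later feature joins
  the **earliest** representative it clears a cutoff against, else starts
  its own group. In a transitive chain a~b~c with a–c below both cutoffs,
  b joins a and c becomes a new representative — every collapsed member is
  guaranteed to clear a cutoff against its own representative. Group
  membership is kept and restored after selection.

### Multiple-covering bagging

With class counts like 6 vs 36 a tree ensemble votes the majority almost
regardless of the genotype. Each bag holds all strains of the smallest class
plus, from every other class, min(`bag_multiplier`·|smallest|, |class|)
strains (default multiplier 2), so the within-bag ratio never exceeds the
multiplier. Draws come from a per-class "unused" pool consumed without
replacement across bags; when the pool is smaller than the quota it is
flushed into the bag, the shortfall drawn uniformly from already-used
strains, and the pool reset. Bags are added until every strain of every
non-smallest class has usage ≥ `cover_l` (default 10; larger values buy
smoother averaged scores at linear cost). In multi-class experiments
"dominant" generalizes to all non-smallest classes and coverage is enforced
for each. When |largest| ≤ multiplier·|smallest| the classes are not
considered disproportionate and a single all-strain bag is used.
Multiple-downsizing (every bag = |smallest| strains per class) is available
as the alternative for very large panels.

### Casewise (local) importance

Per bag, `n_trees` CART trees (Gini, best split over a random √p-sized
feature subset per node) are grown on bootstrap resamples; the bootstrap is
retained per tree. For strain s out-of-bag in a tree, the tree votes once
with the data intact and once per used feature f with f's values permuted
among the tree's out-of-bag strains:

    score(f, s) = mean over trees with s OOB of
                  1[vote = true class, intact] − 1[vote = true class, permuted]

Features a tree never splits on contribute zero from that tree. A strain
never out-of-bag has an undefined (NaN) score, never zero. Impurity-based
importances are not a substitute: the method needs per-strain signs.
Permutations are drawn in a documented order (trees in index order, used
features ascending) so tests can replay them exactly against a brute-force
vote trace.

Trees are grown through scikit-learn's Cython tree builder with the
bootstrap expressed as sample weights — the identical construction
`RandomForestClassifier` uses internally — because at 18-strain bag sizes
per-estimator Python overhead dominates the actual build cost by more than
an order of magnitude. Equivalence of the traversal and vote bookkeeping is
asserted against public-API trees and a hand trace in the test suite.

### Stability, iteration, gating, ranking

Scores and class errors are averaged over bags (per strain, only over the
bags containing it), and the whole classification is repeated `m_runs` = 3
times. A feature is kept only if **in every run** it has positive scores for
at least `min_support_strains` = 3 strains of a single class ("consistently"
is read as all-runs; an any-run mode exists behind a flag). Optionally
`support_fraction` raises the bar to a fraction of the class size, guarding
against chance support by 3 strains of a large class. Kept features feed the
next elimination round; iteration stops when a round removes fewer than
`r_stop` = 5 features. Discarded features do not re-enter later rounds.

A class is reported only if ≥ 60 % (`accuracy_gate`, boundary inclusive) of
its strains are correctly classified by the majority of the bag-averaged
out-of-bag vote fractions; vote ties count as misclassified. Per gated
class, phenotype importance of a feature is the sum of its casewise scores
over the class's strains; the top `top_t` = 50 are reported and every
collapsed group member of a reported representative is appended with the
representative's importance (origin `correlated-added`). The per-strain
correct/incorrect tallies across all bags and runs are reported for outlier
hunting (consistently misclassified strains usually have wrong/ambiguous
phenotypes, noisy genotypes, or sit in a minority class).

### Relation categories

For each reported (feature, class): presence fraction ≥ 0.75
(`presence_cut`, inclusive) → present; ≤ 0.25 (inclusive) → absent;
otherwise partial. This three-state presence is crossed with a two-tier
importance split at the **median phenotype importance of the reported
features of that experiment-class** (≥ median → strong). The tier rule is
the one genuinely open design point in the categorization; the median split
is documented here and isolated in one function so it can be swapped. The
palette is fixed: bright/dark green = present, bright/dark red = absent,
black/grey = partial.

### Correlation baseline

Per feature, Pearson and Spearman correlation against the labels encoded
0/1 (two classes) or by sorted-label rank codes (more), two-sided p-values
(t approximation for Pearson, scipy's exact/AS89-style for Spearman),
Benjamini–Hochberg adjustment per metric, selection at adjusted p ≤ 0.05
(`fdr_alpha`; 0.01 available — it suppresses spurious hits at the cost of
losing all hits for weakly-powered experiments). Zero-variance features are
excluded with a reason. On cleanly penetrant relations the baseline and the
forest agree; the baseline structurally misses partial relations and
imbalance-masked relations.

## CGH normalization and calling

Inputs are per-spot records (probe id, gene id, grid row/col, two channel
intensities); M = log₂(I_sample/I_reference), A = log₂(I_sample·I_reference).
A is written as the plain log product (no ½ factor): it serves only as the
dye-fit regressor, where the factor is an axis rescaling.

* **Spatial correction.** M and A are corrected separately:
  corrected = value − surface + median(value), where the surface is the
  Gaussian-kernel weighted local mean over grid coordinates (normal kernel,
  default bandwidth 5 grid units, exposed as a flag). Implemented exactly as
  the ratio of two Gaussian-filtered grids (sum and count), i.e. an
  untruncated discrete kernel average.
* **Dye-bias correction.** A degree-1 loess (lowess) of M on A, fitted only
  on probes with |M − median(M)| ≤ 1 — the bulk corresponding to present
  genes, so the absent cloud cannot drag the trend — and subtracted from
  all probes via interpolation (constant beyond the fitted range). Default
  span 0.5; fewer than 10 in-band probes is an error.
* **Threshold.** The corrected-M histogram (400 equal bins over the
  observed range) is differentiated with a 21-bin Lanczos low-noise window:
  d_i = 3 Σ_{j=1..10} j (h_{i+j} − h_{i−j}) / (10·11·21·Δ). The per-array
  threshold M* is where d traverses from negative to positive below
  M = −0.5 — the histogram valley between the present peak (M ≈ 0) and the
  absent peak. Two numerical refinements handle sparse valleys: derivative
  magnitudes at or below what one isolated count can produce are treated as
  zero (a single stray probe in an empty valley must not move the
  threshold), and when the traversal spans a run of empty bins M* is the
  midpoint between the last negative and first positive derivative (capped
  at −0.5). Against the analytic minimum of the generating mixture this
  floor+midpoint rule measures sd ≈ 0.04 (vs 0.13 for the literal
  last-negative-bin rule) on default synthetic arrays. If no traversal
  exists, or fewer than 1 % of probes fall below the candidate M*, the
  histogram is declared unimodal and calling refuses rather than guessing.
* **Calls.** Replicate spots of a probe are averaged after normalization;
  probe present iff mean M ≥ M* (boundary inclusive — M* marks the
  absent-side valley; the opposite convention is exercised in tests). Gene
  calls are the majority vote of their probes; exact ties are absent.
  Multiplying both channels by a constant leaves M, hence all calls,
  unchanged.

## Synthetic data

`gen_panel` emulates a strain panel: binary features over n = 40 strains
(classes 6/34 by default, mirroring a strongly imbalanced two-class
experiment), 500 features of which 5 are fully penetrant class indicators,
one 20-member co-inherited block cloning the first causal feature, and the
rest neutral Bernoulli(p) features with p ~ U(0.15, 0.85). Flip noise
(default 2 %) inverts cells independently; block members share their
representative's flips (losing an operon loses all its genes), which keeps
within-block correlation at 1 and is what makes the collapse-and-re-add
machinery testable. Partial relations are generated as complementary pairs
(X, Y) covering a stated fraction of the majority class each, absent from
the minority — either gene suffices for the trait, so neither correlates
strongly with it marginally. What the generator does **not** emulate:
phylogenetic population structure (strains are exchangeable), linkage
beyond the planted block, genotype-calling error correlated across genes,
or multi-experiment phenotype correlation. Passing recovery tests therefore
demonstrates the machinery, not robustness to lineage effects in real
panels.

`gen_cgh` emulates one hybridization of a single-reference bacterial
platform: ~2800 genes × 3 probes, each spotted in duplicate (~17k spots)
on a 132×132 grid; present genes draw probe M ~ N(0, 0.3), absent genes
(15 %) M ~ N(−3, 0.3); a smooth planted spatial surface (amplitude 0.6) is
added to M and A, and a smooth A-dependent dye trend (amplitude 0.4) to M,
before intensities are reconstructed. The absent-peak mean of −3 mirrors
the deep minor peak real arrays show; array size matters — at a few hundred
genes the histogram valley is too sparse for the 400-bin estimator to be
accurate, so the defaults match the platform scale.

## Problem sizes and determinism

Default desk-scale settings: `n_trees` = 200 per bag (100 in the heavier
recovery studies; score rankings stabilize well below that at these bag
sizes, and doubling trees mainly narrows the casewise score noise),
`cover_l` = 10, `m_runs` = 3. The recovery study uses 20 seeded panels of
40×500; the CGH study 10 seeded arrays. All randomness flows from one seeded
`numpy` generator recorded in the run manifest; rerunning with the manifest's
seed reproduces every TSV byte-for-byte.

## Known limitations

* Casewise scores are undefined (NaN) for strains never out-of-bag; with
  very few trees whole strains can drop out of the support counts.
* The stability rule's all-runs reading is conservative: a genuinely weak
  feature supported in 2 of 3 runs is discarded.
* The importance tier split (median of reported features) is a convention;
  relation categories in the strong/weak dimension are only comparable
  within one experiment-class.
* Greedy correlation grouping depends on input feature order (documented,
  deterministic); a clustering formulation would be order-free but could
  not guarantee the member-vs-representative cutoff invariant.
* Equal-width phenotype binning preserves measurement magnitude but can
  produce thin bins under skew; quantile binning is deliberately not the
  default.
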