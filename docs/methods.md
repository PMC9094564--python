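# Methods

This note documents the model, the conventions chosen where the design was
genuinely open, the synthetic-data generator and what passing tests do and
do not establish about real data.

## Classifier

The classifier is a random forest of `n_trees` CART trees (defaults:
1,000 trees, `max_depth = 15`, `min_samples_leaf = 1`, Gini splitting,
`⌊√p⌋` candidate features per node). Class imbalance — typically hundreds
of positives against tens of thousands of negatives — is handled inside the
ensemble rather than by global reweighting: each tree receives its own
balanced bootstrap of *n* draws with replacement from each class, with *n*
the size of the smallest class. The per-tree sample multisets are stored in
the trained model; they are what makes out-of-bag logic possible later.

**Score.** A variant's score is the mean over trees of the class-1 fraction
of the leaf it reaches (a soft vote). With near-pure leaves this coincides
with the fraction of trees voting "regulatory", and unlike a hard majority
vote it makes the additive decomposition below hold exactly.

**Indels.** An indel is scored per position: the affected reference
positions plus one flanking position on each side, each evaluated for both
substitution classes (transition and transversion); the maximum of all
these scores is reported, with the full per-position trace retained.
Convention (the underlying biology does not dictate one): a deletion's
affected positions are the deleted bases — the REF bases beyond the shared
prefix with ALT — and an insertion's affected position is its anchor base.
A 2-bp deletion therefore evaluates 4 positions / 8 scores, a 1-bp
insertion 3 positions / 6 scores.

**Feature importance** is the mean decrease in Gini impurity per feature,
averaged over trees and normalised to sum to 1.

## Feature schema

The feature compendium is configuration, not code: a YAML schema lists each
feature's name, group (sequence / conservation / functional genomics /
enhancer–gene association), dtype, missing value, aggregation rule and
source track. The shipped default has 41 features: 5 sequence features
(CpG dinucleotide and island flags, a 3-way variant-type encoding), 7
conservation features (two phyloP and two phastCons variants, GERP score
and element flag, a context-dependent tolerance score), 25 functional
genomics features (18 chromatin-state cell-type counts, 3 median histone
fold-change signals, conserved and clustered TFBS, DNase clusters) and 4
enhancer–gene features (region overlaps and an evidence count).

Aggregation over overlapping track records: maximum for continuous
features (e.g. the best motif score among overlapping TFBS clusters),
logical OR for binary overlaps, count for evidence tallies, median for
cell-type signal stacks. Sparse per-cell-type chromatin-state calls are
aggregated into per-state cell-type counts, since forests exploit dense
counts far better than one-hot sparse states. Missing values encode
absence of evidence as 0 for every feature family; the value is recorded
per feature in the schema so the policy is auditable.

**Biotype priority.** When gene segments overlap, a variant's single
biotype is the most constrained interpretation:
CDS > splice site > UTR > promoter > non-coding exon > intron; no overlap →
intergenic.

## Negative-control sampling

* `random`: uniform without replacement from the (non-coding SNV) pool.
* `local`: all pool variants within 1,000 bp of at least one positive
  (exhaustive by default, with an optional per-positive cap); positives
  recruiting no negative are reported as dropped.
* `adjusted`: negatives restricted to cytogenetic bands containing at least
  one positive; per-biotype counts matched to the positive biotype
  proportions using largest-remainder quotas so counts sum exactly to the
  request. Draws are without replacement. The proportion-matching contract
  (max |fraction difference| ≤ 0.01 by default) applies when no biotype
  stratum exhausts its eligible pool; exhausted strata are under-filled
  with a warning and their positives flagged.

## Evaluation

Folds are assigned to cytogenetic bands (seeded shuffle, then greedy
assignment of bands to the currently smallest fold), and variants inherit
their band's fold; two variants of one band can never straddle train and
test. ROC AUC uses the trapezoidal rule (equal to the tie-corrected
Mann-Whitney U statistic normalised by n₊·n₋, which the tests verify
against an independent pair-counting oracle); PRC AUC uses step-wise
interpolation (average precision), which avoids the optimistic bias of
linear interpolation in PR space. The decision threshold is the smallest
observed score value maximising F1 (predict positive at score ≥ t). Mean
CV curves are produced by vertical averaging on a fixed 101-point grid with
a mean ± 1.96·SD band across folds — one reasonable construction of a 95%
band; others exist.

Cross-scheme evaluation applies each scheme's per-fold models to the other
schemes' datasets, restricting each partial model to test variants whose
band lies in its held-out fold, and subsampling negatives per fold so
positives form 12.5% of each test subset, making curves comparable across
schemes with different class ratios.

## Feature contributions

Contributions use decision-path value decomposition (the semantics of the
`treeinterpreter` approach): walking a variant's path in one tree, the
change in the node class-1-fraction estimate from parent to child is
credited to the feature the parent splits on; the bias is the root
fraction. Summed and averaged over trees this gives the exact identity
`score = bias + Σ contributions`, asserted at 1e-9 on every computed
vector and verified against a brute-force path-enumeration oracle on small
forests. An alternative reading — crediting Gini impurity decreases — does
not produce an additive per-variant decomposition and is not implemented.

For training variants, only out-of-bag trees (whose bootstrap excluded the
variant) are used; with *n* balanced draws from a class of size *N*, a
variant is out of bag for a given tree with probability (1 − 1/N)ⁿ ≈ e⁻¹,
so roughly a third of the forest remains, which the tests check. A variant
present in every tree's bootstrap falls back to all trees with a warning
and `oob = false`.

Functional profiles rescale raw feature values into [−1, 1] by their
empirical quantile position in a reference (background) distribution —
minimum → −1, median → 0, maximum → +1, linear in rank space between
observed values. The quantile map was chosen over min-max scaling for
robustness to the heavy tails of conservation scores.

## Clustering and effect sizes

K-means runs on the positive variants' contribution vectors for K in a
range (default 2–19), 10 restarts per K, best inertia kept. K is selected
by silhouette maximisation; the inertia curve is reported alongside for
elbow inspection. (A joint silhouette/inertia criterion is not an
algorithm; when the two disagree, silhouette decides.) Clusters are
characterised against everything else (other clusters plus negatives) by
Cohen's d (pooled-SD standardised mean difference) for discrete and
continuous features and Cohen's h = 2(arcsin √p₁ − arcsin √p₂) for binary
features, where a binary feature's proportion is the fraction of variants
with a nonzero raw value. Zero pooled SD yields a signed-infinity flag
rather than an exception.

## Ranking

Regulatory-region resources merge by interval overlap (1 bp suffices;
adjacency does not merge under half-open coordinates) into maximal regions
whose target-gene and evidence sets are unions over constituents; a
resource carrying per-pair scores can be flagged pass-through and kept
unmerged. A variant belongs to a region if its point position (SNV) or any
evaluated position (indel) falls inside. Disease-gene filtering keeps
variants in regions whose targets intersect the supplied gene list, then
ranks by score with ties broken by (contig, position, alt allele) so
ranking is deterministic. The spike-in benchmark pools each pathogenic
variant with the background, filters per disease, and reports the
spike-in's rank and the candidate-set size; spike-ins in no region
targeting their disease gene are reported as unrankable rather than
silently dropped.

## Synthetic data

The generator produces, from a single seed: contigs tiled exactly by
cytogenetic bands; genes with promoter (2 kb upstream of the TSS), UTR,
CDS/intron or non-coding-exon segments; regulatory regions anchored near
promoters with 1–k target genes; and two variant classes. Three properties
of real training data are reproduced because the method's design responds
to them:

1. **Biotype imbalance** — positives are placed gene-proximally (≈45%
   promoter, ≈35% gene body, ≈20% near-gene) while the benign pool is
   uniform; this is what motivates biotype-matched sampling.
2. **Class-conditional shifts** — a configurable set of features (default:
   5 conservation scores) gains `effect_size` standard deviations in
   positives. The shift is added after all random draws, so two configs
   differing only in effect size share identical positions and noise.
3. **Spatial autocorrelation** — variants in the same window (default
   50 kb) share a latent Gaussian noise component on the informative
   features, and positives arrive in clusters around anchor genes. This is
   the minimal mechanism that makes random-split CV optimistic relative to
   band-aware CV.

Track-based annotation is also supported: the generator emits one BED track
per schema source, with informative conservation tracks carrying short
elevated intervals centred on positive variants, so annotating from files
recovers the class signal (and negatives within a few bp inherit part of
it, as in real data).

**What the generator does not emulate:** realistic nucleotide sequence,
realistic marginal distributions of conservation scores and chromatin
signals, correlated feature structure beyond the shared window noise, and
the long-tailed sizes of real regulatory domains. Passing tests therefore
demonstrate the correctness of the machinery (sampling contracts, exact
decomposition, leakage direction, rank behaviour under controlled
separation) — not the accuracy the method would reach on real clinical
data.

## Problem sizes and numerical choices

Experiment conditions are fixed in `regvar.workflows`:

* Parameter recovery: generator defaults (2 × 10 Mb, 40 bands, 200 genes,
  800 positives, 50k pool, d = 3 on 5 features), adjusted negatives at a
  12.5% positive fraction, 300-tree forests, band-aware 10-fold CV.
  Ensemble averaging has converged well before 300 trees; the run takes
  tens of seconds on one CPU.
* Leakage comparison: a deliberately unsaturated regime (d = 0.8, window
  noise SD 2.0, positive clusters of 8, 150 positives) on a 2 × 2 Mb
  genome, 60-tree forests, 5 folds, 10 seeded repeats; at d = 3 both fold
  schemes saturate near AUC 1 and the gap is invisible.
* Spike-in benchmark: 2 × 2 Mb genome, 200 regions, 100-tree forest, half
  the positives held out as spike-ins, effect sizes {0, 1, 3}.

Floats in text outputs carry 6 significant digits; the decomposition
identity is exact in memory (≤ 1e-15) and limited only by file precision
after a TSV round trip. Seeds feed `numpy.random.default_rng` and per-tree
scikit-learn `random_state` values derived via `SeedSequence`; every
sampler, forest and experiment is bit-reproducible given its seed. Interval
logic is 0-based half-open throughout, with VCF's 1-based positions
converted on ingest; `chr` prefixes are stripped for matching and preserved
on output.

## Known limitations

* The 41-feature default schema mirrors the named feature families
  generically; it is a structural stand-in, not a curated annotation
  compendium, and real use requires supplying real tracks via the schema.
* Local sampling uses SNV point distance; indels are excluded from training
  pools.
* Cross-scheme evaluation assumes the schemes share one positive set and
  one band partition.
* The hyperparameters are accepted as given; no nested-CV search harness is
  included.
* Pass-through region resources keep their per-pair records but no
  per-pair scoring rule is applied downstream.
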