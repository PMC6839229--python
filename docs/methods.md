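# Methods

## Input model

The unit of analysis is a continuous sample-by-gene matrix `M_c`
(m samples × n genes): expression, methylation or any per-gene
quantitative alteration score, with unique sample and gene IDs. Mining
operates on its binarization `M_b` (same shape and labels, entries in
{0,1}), where 1 encodes a per-sample "molecular event" — the gene is
dysregulated in that sample. `M_b` doubles as the transaction database:
samples are transactions, genes are items.

Genes with any missing value are dropped before binarization
(`drop_missing_genes`); when a matrix is too wide to mine, `select_top_genes`
keeps the n highest-scoring genes, using an externally supplied ranking
(e.g. a differential statistic computed upstream) or, as a neutral
fallback, per-gene variance. Differential-expression/-methylation
testing itself is deliberately out of scope — the tool accepts any
pre-ranked or raw matrix.

## Discretization

Five per-gene binarization rules are provided (`Discretizer`;
thresholds act per gene across samples):

| method | event condition | threshold meaning | default |
|---|---|---|---|
| `zscore` | \|z\| > t (direction-restricted) | z-score cut | t = 1.96 |
| `quantile` | value strictly outside the (q, 1−q) empirical quantiles | tail mass q ∈ (0, 0.5] | — |
| `top_fraction` | \|value − median\| among the ⌈f·m⌉ largest | fraction f ∈ (0, 0.5] | — |
| `mean_sd` | \|value − mean\| > t·SD | SD multiples | — |
| `fixed` | value > t (up), < −t (down), \|value\| > t (both) | raw cut | — |

The default — two-sided z-score at 1.96 — flags roughly 5% of samples
per gene under normality, the conventional two-sided 5% cut. Design
choices made for determinism: quantile ties resolve to 0 (strict
inequality at the cut); `top_fraction` selects by absolute deviation
from the median with `up`/`down` restricting the sign of the selected
samples; `fixed`'s `down` means below −t. These keep every method
consistent with two structural properties the test suite asserts: the
`up` and `down` outputs OR together to the `both` output, and
discretization commutes with gene permutation. A constant gene cannot
be z-scored; its column becomes all 0 with a warning rather than an
error. `Discretizer` is a scikit-learn transformer: statistics are
learned in `fit` and applied in `transform`, so it composes with
pipelines; the `discretize()` function is the one-shot fit-and-apply
path used throughout the CLI.

## Mining

`AssociationRuleMiner` implements exact, level-wise Apriori: per-item
boolean sample masks, canonical prefix-join candidate generation, and
anti-monotone pruning (any candidate with an infrequent subset is
discarded before counting). Output is exactly the itemsets with support
≥ `min_support`, with exact supports — verified in the tests against a
full power-set enumeration, which is tractable at the tool's intended
scale (≤ ~100 genes after top-n selection; the exhaustive cross-check
runs at ≤ 12 genes).

Rules `X => Y` are induced from every frequent itemset `Z = X ∪ Y`
(all supports of subsets are available by anti-monotonicity), keeping
those with `|Y| ≤ max_rhs` and confidence ≥ `min_confidence`. Defaults
mirror common practice for cohort-scale omics mining: `min_support`
0.3, `min_confidence` 0.8, `max_rhs` 1 (single-item consequents, the
classical rule-induction convention; multi-item consequents by flag).
All orderings (itemsets by size then lexicographic items; rules by
support desc, confidence desc, then lexicographic sides) are
deterministic across platforms. `generate_rules` recounts each supplied
itemset's support against the matrix and raises on any mismatch, so a
stale or foreign frequent-itemset list cannot silently corrupt rule
metrics.

## Lamda3

For a rule `A => C` with single genes on both sides, `M_b` splits the
samples into three parts: both genes 1 (`both_one`), both 0
(`both_zero`), and the inconsistent remainder. The inconsistent part is
computed and reported in `SamplePartition` but does not enter the
score. Within `both_one` and `both_zero`, on the *continuous* values:

- `p2_ac`, `p0_ac` — two-sided correlation-test p-values of (A, C);
- `p2_bg`, `p0_bg` — the median of the p-values of A against every
  other gene in the matrix (all genes except A and C, not only genes
  that appear in rules);

and

```
Lamda3 = (log10 p2_ac + log10 p0_ac) / (log10 p2_bg + log10 p0_bg)
```

Pearson correlation is the default (the conventional default of `cor`
style tests); Spearman is available for monotone-but-nonlinear signal.
Numerical guards, chosen to avoid fabricated scores rather than to
extend the formula's domain:

- p-values are clamped to [1e-300, 1] before the log, so a numerically
  zero p-value cannot produce −∞;
- a correlation on fewer than 3 points, or involving a constant vector,
  is given p = 1 (no evidence) — and a rule whose `both_one` or
  `both_zero` partition has fewer than 3 samples gets Lamda3 = NA
  outright, as does a rule with no background gene or with both
  background medians exactly 1 (denominator 0). NA propagates to the
  ranking, where NA-valued rules sort last.

Only the 1→1 case has a printed definition; observed practice still
ranks rules with multi-gene antecedents. The implementation evaluates
the 1→1 formula for every (antecedent gene, consequent gene) pair and
reports the lower median of the defined pair values — the lower median
(index ⌊(k−1)/2⌋ of the sorted values) rather than an interpolated one,
so the reported breakdown (its four p-values) always belongs to an
actual pair. Pairs with NA are excluded; if every pair is NA the rule's
Lamda3 is NA. This degrades gracefully and reduces exactly to the
printed formula for 1→1 rules, but multi-gene Lamda3 values are an
extension and are flagged as such here.

## wcs (weighted condensed support)

The weighted variant of support is implemented as
`support(X ∪ Y) × mean(w_g, g ∈ X ∪ Y)`, with weights in (0, 1]. When a
gene ranking is available, `rank_weights` derives `w_g = (n − rank_g + 1)/n`
(top gene weight 1, last gene 1/n); otherwise weights default to 1 and
wcs equals plain support exactly — the reduction the tests assert. The
exact functional form of this measure is not standardized; this
interpretation is documented here so results are reproducible against
it. Without a supplied ranking, wcs adds no information beyond support,
which mirrors how the measure becomes unavailable when no rank-based
weights exist.

## Ranking

`rank_rules` sorts descending by one measure (support, confidence,
lift, wcs, Lamda3), NA last, with a fixed tie-break chain (lift desc,
support desc, lexicographic LHS, lexicographic RHS) so output is
reproducible across platforms. The ranking API is measure-agnostic, so
an external gene-pair relatedness score (e.g. an annotation-based
similarity) can be attached downstream by filling a metric and ranking
on it; no such evaluation is bundled, as it requires external
annotation databases.

## Multi-omics combination

Two layers measured on the same patients are merged on the intersection
of their sample IDs (compared after whitespace trimming, no barcode
truncation; fewer than 2 shared samples is an error), in layer-1 order.
Layer-1 genes get the suffix `.1`, layer-2 genes `.2`; a gene already
ending in a suffix pattern triggers a warning but is suffixed anyway
(labels stay unambiguous). The combined continuous and binary matrices
are built identically, so mining and Lamda3 scoring work unchanged on
the combined input.

The cross-omics filter keeps rules whose items span both layers. The
"spanning" reading — at least one `.1` and one `.2` item anywhere in
the rule — is the default, because rules with a mixed antecedent and a
layer-1 consequent (e.g. `{TAP1.1, ANXA5.2} => {PSMB9.1}`) are exactly
the mechanistically interesting shape this filter exists to keep. A
`strict` mode (antecedent and consequent share no layer) is available
by flag.

## Graph and grouped views

`rules_to_graph` builds a bipartite digraph: gene nodes and one node
per rule, edges antecedent-gene → rule → consequent-gene. This is
lossless for multi-gene antecedents (no hyper-edges needed) and makes
hub consequents visible as gene nodes with high in-degree. Exports:
GraphML (via networkx) and DOT; metrics are attached to rule nodes
rounded to 6 decimals. `rules_to_grouped_table` clusters antecedent
itemsets — identical antecedents first, then greedy merging of the two
groups with highest Jaccard overlap of their pooled items until at most
`n_groups` remain (ties lexicographic) — and emits one row per (group,
consequent) cell with the rule count and best measure value, the input
for a balloon-style plot. The grouping heuristic is a design choice;
any clustering of antecedents would serve.

## Synthetic data

The generators exist so every pipeline stage can be exercised against
known truth without downloads. Defaults describe one study condition:
m = 60 samples, n = 20 genes, one planted pair with target correlation
0.95, dysregulation fraction 0.5, background noise SD 1. Each planted
pair is driven by one shared standard-normal latent factor plus
independent Gaussian noise with SD `sqrt((1−r)/r)`, which yields
corr ≈ r both inside and outside the dysregulated subset; in the
dysregulated fraction of samples the factor is shifted by +3, and the
binary matrix marks exactly that subset for planted genes. Noise genes
are independent and binarized by the default z-score rule (≈5% events),
so they are infrequent at support 0.3 and form a flat correlation
background. The paired generator puts the two genes of each planted
pair in different layers, with a controllable sample overlap between
layers; a fully deterministic block-design fixture (`toy_paired_layers`)
backs the exact-count multi-omics tests.

What the generators do not emulate — and hence what passing tests do
not establish about real cohorts: realistic marginal distributions
(negative-binomial counts, beta-valued methylation), batch effects,
correlated background modules, or missingness patterns. They establish
correctness of the machinery and detectability of a planted signal
under clean conditions, not field performance.

## Problem sizes in the checks

The exhaustive mining cross-checks run on matrices up to 12 genes × 40
samples (the power-set oracle grows as 2^n); Lamda3 fidelity checks use
30 × 8 matrices; planted-signal recovery uses 50 seeds of the default
60 × 20 condition. These sizes make the oracles exact while keeping
the full suite fast.

## Known limitations

- Apriori only; no FP-Growth/Eclat, closed/maximal condensation, or
  approximate mining. Fine at ≤ ~100 genes, not for thousands.
- No multiple-testing control over rule p-values; Lamda3 is a ranking
  score, not a calibrated significance level.
- Multi-gene-antecedent Lamda3 is a documented extension (pairwise
  lower median) of a measure defined for single pairs.
- Two layers only in the combiner; three or more would be a
  straightforward extension but is not implemented.
- The matrix reader handles labelled delimited text only — no archive,
  array-IDAT or sparse formats.
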