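# Methods

## The model

The pipeline treats schizophrenia gene discovery as a promotion problem:
a large multi-evidence gene pool is split against a curated disease
database into known disease genes (set A) and unvalidated genes (set B),
and set B genes are promoted when (i) they carry case/control expression
signal in brain tissue, (ii) they cluster into a latent expression factor
retained by a variance criterion, and (iii) that factor, pooled with set
A, keeps a disease pathway significantly over-represented while the gene
itself is a member of the pathway. Promoted genes and the set A pathway
genes are then wired into networks through physical interactions, and
highly connected nodes (hubs) are profiled by their evidence support.

## Stage-by-stage choices

**Pool and split.** Gene identity is the uppercased official symbol; no
alias resolution is attempted (a documented limitation — symbols that
differ between sources are treated as different genes). Disease-database
genes absent from the pool are ignored: set A is defined as a subset of
the pool.

**Expression QC.** The low-expression rule keeps genes whose *mean* FPKM
across all samples is ≥ 1 (the aggregate is configurable to the median;
"below threshold in every sample" readings are stricter and discard more).
Collinearity is measured as |Pearson r| on log₂(FPKM+1). Offending pairs
are scanned in descending |r| and the lower-variance member is dropped;
an exact variance tie drops the lexicographically later symbol so the
filter is deterministic. After pruning, no surviving pair exceeds the
threshold (asserted in tests by recomputing the full correlation matrix).
Constant genes have undefined correlation and are treated as r = 0 with a
warning; constancy is detected as row-min == row-max rather than
variance == 0, which accumulates floating-point error.

**Random forest.** 1,000 trees, impurity-based importances (normalized to
sum to 1), scikit-learn defaults otherwise, seed surfaced in every API.
The filter removes only genes with *exactly zero* importance. With
1,000 trees and ~10² samples this filter is permissive — most genes are
selected in at least one split — which matches its published use as a
coarse noise screen ahead of factor analysis rather than a hard selector.

**Factor analysis.** Maximum-likelihood factor analysis
(`sklearn.decomposition.FactorAnalysis`) on genes standardized from
log₂(FPKM+1), with the number of components capped at
min(n_samples − 1, n_genes, 30). The `factor_analyzer`-style principal-axis
option was not used; ML factoring exposes the same loading/rotation
interface and is deterministic here. Factors are ordered by their
explained-variance proportion (sum of squared loadings / number of genes)
and the retained set is the shortest non-empty prefix reaching the 70%
cumulative target — all factors when the target is never reached, which
is the common case when many weak factors each explain little variance.
Varimax rotation is applied **after** selection and only to the retained
block: rotating all components first lets varimax split a dominant
general factor across components (its criterion penalizes columns with
uniformly high loadings), which breaks the one-latent-factor recovery
case. The rotation itself is the standard Kaiser iteration implemented
in-package (no installed library exposes standalone varimax).
Gene-to-factor assignment takes the retained factor with maximal
|loading|, requires |loading| ≥ 0.3, and breaks exact ties toward the
lower factor index.

**Enrichment.** One-sided hypergeometric upper tail via
`scipy.stats.hypergeom.sf` (log-space internally; p-values down to
~1e-242 verified not to underflow), BH step-up implemented in-package and
cross-checked against `statsmodels.multipletests` in tests. The BH family
is all pathways in the supplied database per query. The background is the
full gene pool, as the enrichment stage's published description states;
restricting the background to the pathway universe
(`restrict_background_to_universe`) is available but not the default —
on the curated candidate fixture it inflates the expected overlap to the
point where genuinely disease-dense pathways are no longer significant.
The seed-pathway persistence rule re-tests each factor ∪ set A query at
the same q ≤ 0.05 threshold used for seed discovery (both thresholds are
arguments).

**Network.** Edge identity is the (set A gene, set B gene, pathway)
triple; duplicate interaction evidence lines collapse to one edge.
Interactions are undirected and self-pairs are dropped. Hub degree counts
*distinct partner genes* across the union network, not per pathway; a hub
needs degree ≥ 2. Effect directions are deliberately not modelled —
evidence sources conflict on direction, and reconciling them is out of
scope.

## The synthetic generator

Expression: per gene g in factor k and sample s,
x₉ₛ = exp(b₉ + λ₉·F₍ₖₛ₎ + ε₉ₛ) with b₉ ~ N(1.5, 0.6²),
λ₉ ~ U(0.5, 1), ε ~ N(0, 0.7²) and factor scores F ~ N(±effect/2, 1)
(sign by case/control status for informative factors). This yields
positive, right-skewed FPKM-like values. The defaults — 2,000 genes,
60/60 samples, 5 factors × 40 genes, 2 informative, effect size 1.0 —
define the standard recovery scenario used in tests. `noise_sd = 0.7`
bounds the within-factor population correlation at
λᵢλⱼ/√((λᵢ²+σ²)(λⱼ²+σ²)) ≤ 1/1.49 ≈ 0.67, safely under the 0.8 QC
threshold so the collinearity filter does not consume planted signal;
`fpkm_location = 1.5` keeps essentially all genes above the FPKM ≥ 1
floor. Genes outside any factor are independent log-normal noise of
comparable total variance.

Knowledgebase: the pool (default 2,600 genes, ~9% in the disease db)
contains the 2,000 expressed genes plus unexpressed pool genes. Five
disease pathways draw ~70% of their members from the disease db; planted
candidates (8, sampled from informative-factor genes) are written into
them round-robin; the remaining members — and all background pathways —
are drawn from *unexpressed* pool genes when the expression universe is
supplied. This mirrors real pathway databases (most members of any
pathway are not expressed in one tissue) and makes exact candidate
recovery well-defined: the only pathway members the factor stage can
select are the planted ones. The first 4 planted candidates additionally
receive interaction edges to two distinct disease-db members of their
pathway, making them recoverable hubs. Evidence flags are independent
Bernoulli draws with marginal rates matching a ~6,000-gene evidence pool
(e.g. exome 3,540/5,948, GWAS 460/5,948); all-false rows get one
rate-weighted flag forced on, preserving the pool invariant. Expression
and knowledgebase use separate RNG streams (their own seeds), so changing
one block does not perturb the other.

What the generator does **not** emulate: batch effects, library-size or
GC biases, ancestry structure, correlated evidence flags, directional
effects, and pathway overlap structure beyond random sharing. Passing the
recovery tests therefore shows the pipeline's logic is sound under its
own model assumptions, not that real tissue data would behave as cleanly.

## Label-permutation behaviour

Case/control labels influence the pipeline through exactly one stage: the
random-forest importance filter. Factor analysis is fitted on the entire
sample set, and both enrichment stages are label-free. Because the
zero-importance filter is permissive (see above), permuting the labels
does *not* remove the planted candidates — their factor structure is a
property of the expression covariance, not of the labels — and candidate
recovery survives permutation. The permutation control is therefore
asserted where labels act: with true labels ~98% of informative genes
rank in the top importance decile, while under permuted labels that
fraction collapses to ~4% and the importance mass on informative genes
falls to its null expectation (~genes/total). A pipeline variant that
retains factors by case/control discrimination rather than raw variance
would make candidate recovery itself label-sensitive, but the variance
criterion is the documented design.

## Problem sizes and determinism

The standard recovery scenario (2,000 × 120 matrix, 1,000-tree forest,
30-component factor model) runs in a few seconds on one CPU; the full
test suite, including two forest fits and the exhaustive hypergeometric
enumeration oracle (all configurations with background ≤ 12), completes
in well under a minute. Every stochastic step takes an explicit integer
seed; identical configurations and seeds yield bit-identical matrices,
knowledgebases and results.

## Known limitations

- Symbol-string gene identity; no alias/ID mapping.
- The FPKM < 1 aggregation rule and the collinearity metric are this
  package's documented readings; other readings are exposed as options
  but change the surviving gene set.
- Factor count and the |loading| ≥ 0.3 assignment rule are pragmatic
  conventions; published gene-per-factor counts cannot be reproduced
  without the original expression data, so only the assignment *logic*
  is testable.
- Hub evidence percentages depend on the hub set's denominator;
  published percentage figures are not reproducible from the curated hub
  table alone and are not asserted.
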