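# Methods

`pugene` infers disease-associated genes that a biomedical knowledge
graph does not yet link to a disease. This note documents the model,
the estimators, the synthetic benchmark, and the numerical choices.

## Problem setting

A heterogeneous knowledge graph records typed nodes (Disease, Compound,
Gene, ontology terms such as EFO) and typed, undirected relationships.
A gene explicitly linked to a disease through a compound (a
Disease–Compound–Gene path) carries positive evidence; a gene without
such a path is *unlabeled*, not negative — the association may simply be
undiscovered. This is the positive–unlabeled (PU) classification
setting: the training data contain labeled positives and a mixed bag of
hidden positives and true negatives, with no reliable negative labels.

Two fixed metapaths define the dataset for a query disease (one or more
concept identifiers, CUIs):

* **positives** — genes on a Disease–Compound–Gene path of length 2 from
  any query CUI (a direct disease–gene edge does not qualify);
* **unlabeled** — genes that share an ontology term with a positive gene
  (Gene–term–Gene), excluding the positives themselves.

Features are binary indicators: `X[i, j] = 1` iff gene *i* is adjacent
to ontology term *j*, where the feature space is the set of terms that
bridge at least one positive to at least one unlabeled gene. The matrix
is stored CSR; all row/column orderings are lexicographic (positives
first), so the dataset is byte-reproducible regardless of input row
order. All-zero feature rows are kept (dropping genes would silently
change *n*) and logged.

## SCAR and the class prior

Let `f_p` be the density of classifier scores for labeled positives and
`f_u` for unlabeled genes. Under SCAR (labeled positives are a uniform
random subsample of all positives, independent of attributes), the
unlabeled score density is the two-component mixture

    f_u = alpha * f_p + (1 - alpha) * f_n,

where `alpha` is the fraction of hidden positives among the unlabeled
and `f_n >= 0` is the (unknown) negative density. Since `f_n >= 0`,
every feasible `alpha` satisfies `alpha * f_p <= f_u` pointwise. The
identifiable estimand is the *largest feasible mixing proportion*

    alpha_hat = max { a : err(a) <= tolerance },
    err(a) = ∫ max(0, a * f_p(s) - f_u(s)) ds,

with the tolerance sized to density-estimation noise (below). This is
conservative in the usual mixture-proportion sense: it equals the true
`alpha` when negatives vanish somewhere positives live (true here:
negative genes essentially never score in the positive range).

### Scores

Out-of-fold probabilities from gradient-boosted trees (XGBoost;
depth 6, 200 rounds, learning rate 0.1, logistic objective, `hist`
method, single thread). Stratified k-fold cross-fitting guarantees each
gene is scored by a model that never saw it; a fold that loses a class
triggers one reshuffled retry, then a hard error. The hyperparameters
are fixed and documented rather than tuned; class-imbalance weighting
is off by default.

### Bounded density estimation

Scores live on [0, 1] and pile up near the boundaries, so a naive KDE
leaks mass. `bounded_kde` bins scores onto a uniform grid (1,001
points), smooths with a Gaussian kernel using **edge-inclusive
reflection** at 0 and 1, and renormalizes to trapezoid-integral 1.
Edge-inclusive reflection matters: reflection modes that exclude the
boundary sample silently lose ~half the mass of a spike sitting exactly
at 0 or 1 — for typical PU score distributions (a large negative spike
at 0) that loss, after renormalization, inflates the tail of `f_u`
by >20% and biases `alpha_hat` upward by several points. Bandwidth is
Silverman's rule, floored at two grid steps; a degenerate sample
becomes a narrow spike, not a delta.

Inside `estimate_alpha` both densities use a **common** bandwidth taken
from the positive scores. Two reasons: smoothing is linear, so equal
kernels preserve the mixture proportionality `f_u = alpha f_p + ...`
exactly, while per-sample bandwidths distort the ratio; and Silverman's
min(SD, IQR/1.34) rule collapses to ~0 on the heavily skewed unlabeled
sample (most mass at one point), which would leave `f_u` an unsmoothed
histogram.

### Feasibility tolerance

The observed excess `err(a)` is never exactly zero, so feasibility is
judged against the excess expected from sampling noise alone. With
pointwise bootstrap SDs `s_p`, `s_u` of the two KDEs (100 multinomial
resamples each) and the combined scale
`sigma(s, a) = sqrt(a^2 s_p^2 + s_u^2)`, the expected excess if the
truth were the *nearest feasible* density `min(a f_p, f_u)` is, per
grid point, the one-sided Gaussian mean
`sigma * phi(z) - slack * SF(z)` with `z = slack / sigma` and
`slack = max(0, f_u - a f_p)`. The reported estimate is the largest
grid `a` whose observed excess stays below that expectation plus one
bootstrap standard error of the excess statistic. The SE margin keeps a
fully feasible configuration (unlabeled scores distributed exactly like
positive scores) from being rejected by a coin-flip fluctuation; the
expectation term makes the rule unbiased at the feasibility boundary.

### Uncertainty

`estimate_alpha(..., return_se=True)` also reports the SD of the
feasibility crossing over the bootstrap density pairs. Repeated
iterations reshuffle folds over the *same* genes, so the spread of
per-iteration alphas alone understates sampling uncertainty — it would
shrink to zero with more iterations while the gene-sampling error stood
still. The aggregate 95% interval therefore combines both scales:

    mean(alpha_i) +/- 1.96 * sqrt( Var(alpha_i)/m + mean(se_i^2) ),

clipped to [0, 1]; a single iteration degenerates to a point interval.
This interval is deliberately conservative (the bootstrap double-counts
realized noise by up to sqrt(2)), trading width for replicate-level
coverage of the true prior.

### Cross-check estimator

`elkan_noto_alpha` implements the classical SCAR ratio
`clip(mean(scores_unl) / mean(scores_pos), 0, 1)`. It is exact only
when negatives score ~0; with overlapping score components it is biased
upward by `(1 - alpha) * E[s | negative] / E[s | positive]`. It serves
as an independent cross-check in the separable limit, never as the
implementation.

## Calibration and imputation

Calibrated probabilities are a monotone, rank-preserving transform of
the unlabeled scores whose mean equals `alpha_hat` to 1e-6: scores map
to tie-averaged normalized ranks `u` in (0, 1], and `u**gamma` is
solved for `gamma` by bisection. The power transform is strictly
monotone (the top-k report is invariant to it), cannot saturate at 1
the way a clipped linear rescale would, and handles the all-ties case
exactly (the constant `alpha` vector is the unique monotone solution).
`alpha = 0` and `alpha = 1` return all-zeros / all-ones.

The probable-positive set is the `ceil(alpha * |U|)` genes with the
highest **mean** calibrated probability over iterations (mean alpha,
mean probabilities — not per-iteration sets), ties broken
lexicographically by gene id.

## Evaluation design

Because no negative labels exist, the headline metric is **recall on
the originally-labeled positives**: the fraction whose out-of-fold
probability reaches the decision threshold (0.5 by default,
configurable). Model 1 trains with labeled positives as class 1 and all
unlabeled as class 0; Model 2 additionally flips the imputed probable
positives to class 1 during training, but recall is still computed only
over the originally-labeled positives, so the comparison is not
circular. With an empty imputed set and shared seeds, Model 2 is
bit-identical to Model 1. Both run repeated stratified k-fold CV
(defaults 5 folds; iteration count configurable) with
normal-approximation 95% CIs over iterations (percentile bootstrap
available). Precision against the training labels and AUROC are
reported as auxiliary diagnostics only.

## Synthetic benchmark

The generator emulates the pipeline's data regime in miniature and
plants the ground truth the estimators are judged against:

* a disease node wired Disease–Compound–Gene to exactly the *labeled*
  positive genes (one compound per labeled positive by default);
* every gene draws Gene–term edges per term as Bernoulli —
  `p_feature_pos = 0.3` for true positives (labeled *and* hidden),
  `p_feature_neg = 0.05` for negatives, 200 terms by default;
* labeled positives are a uniform random subsample of true positives,
  so SCAR holds by construction (verified by a rank test on per-gene
  feature counts);
* every unlabeled gene is guaranteed to share a term with a labeled
  positive (isolated genes are re-wired, logged), so the metapath
  labeler recovers exactly the planted pools.

Default pools are 1,000 labeled / 2,000 unlabeled with planted
contamination 0.3 (`SyntheticSpec.from_pool_sizes` hits requested pool
sizes exactly; it also resolves the parameterization degeneracy at
`alpha_true = 0`, where any number of fully-labeled positives is
consistent). The binary-feature signal is strong, so classes are nearly
separable; real graphs have weaker, correlated features, richer
ontology topology, and plausible SCAR violations (well-studied genes
are more likely to be labeled *and* better annotated). Passing tests
therefore demonstrate correctness of the machinery and recovery under
the stated assumptions, not performance on any real knowledge graph.

## Problem sizes in the test suite

The acceptance-style tests run the study conditions at 10 generator
replicates x 10 PU iterations per contamination level (0.1 / 0.3 / 0.5)
with a +-0.07 recovery tolerance, and the model comparison at 40
iterations; these sizes keep the suite within a routine CI budget while
leaving the estimators' error well below the tolerances. Unit tests use
a reduced learner (depth 3, 30 rounds) for plumbing checks such as
determinism, where the learner's strength is irrelevant.

## Known limitations

* The alpha estimator's CI is conservative (over-covers); its width is
  dominated by the bootstrap term, not iteration spread.
* The excess-mass estimand is an upper envelope: if negatives score
  everywhere positives do (no anchor region), it overestimates.
* Undirected, relation-type-agnostic traversal is assumed throughout;
  relation types are kept only for filtering and provenance.
* The two metapaths are fixed; no general metapath templating.
* Feature terms are binary indicators; no edge weights or counts.
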