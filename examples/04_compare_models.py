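"""Quantify the gain from PU imputation: Model 1 vs Model 2.

Model 1 is the naive baseline (all unlabeled genes treated as
negatives). Model 2 re-labels the imputed probable positives as class 1
before training. Recall is computed only on the originally-labeled
positives, so the comparison is not circular: if the imputed genes were
noise, pulling them into class 1 would blur the boundary and recall
would not improve.
"""

from pugene import (
    EvalConfig, SyntheticSpec, make_pu_dataset, run_model1, run_model2,
    run_pu_iterations,
)

spec = SyntheticSpec.from_pool_sizes(
    n_labeled=300, n_unlabeled=600, alpha=0.3, n_terms=100, seed=7
)
dataset, truth = make_pu_dataset(spec)
_, scores = run_pu_iterations(dataset, n_iterations=5, n_folds=5, base_seed=1)

config = EvalConfig(n_folds=5, n_iterations=10, base_seed=2)
r1 = run_model1(dataset, config)
r2 = run_model2(dataset, scores.imputed_positives, config)

for r in (r1, r2):
    lo, hi = r.recall_ci95
    print(f"{r.model_name:26s} recall {r.recall_mean:.4f} (95% CI {lo:.4f}, {hi:.4f})"
          f"   AUROC {r.auroc_mean:.4f}")
# Model 2's recall on the *original* labeled positives should exceed
# Model 1's: cleaning hidden positives out of the negative class lets
# the classifier draw a sharper boundary.
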