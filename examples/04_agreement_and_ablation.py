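"""Classifier-agreement set algebra and the cumulative feature-group ablation.

Agreement rows report, for a classifier pair (A, B), the percentage of
samples A got right, B got right, both (A&B), either (A|B), and each
exclusively (A-B, B-A) — low overlap with high union is what makes a pair
worth ensembling.  The ablation adds feature groups one at a time and
re-runs random-forest cross-validation.
"""

import oncotyper as ot

config = ot.default_config("tiny")
variants, cnv, labels, _ = ot.simulate_cohort(config)
matrix = ot.assemble_matrix(variants, cnv, labels, ot.schema_for(config))

mlp = ot.MlpConfig(hidden_layers=2, units_per_layer=64, learning_rate=1e-3,
                   batch_size=32, max_epochs=50, seed=0)
report = ot.nested_cv(
    matrix, labels, methods=("lsvc",), k_grid=[40], seed=7,
    n_outer=5, n_inner=3, mlp_config=mlp,
    rf_config=ot.RandomForestConfig(n_trees=100),
    extra_members=("ovr_svm", "knn"),
)

names = ["mlp", "random_forest", "ovr_svm", "knn"]
print("pairwise agreement (percent of samples):")
for i, a in enumerate(names):
    for b in names[i + 1:]:
        row = report.agreement(a, b).as_row()
        print(f"  {a:>13} vs {b:<13} " + "  ".join(f"{k}={v:5.1f}" for k, v in row.items()))

print("\ncumulative feature-group ablation (random forest, 3-fold CV):")
for groups, acc in ot.ablation_study(matrix, labels, seed=7, n_folds=3, n_trees=100):
    print(f"  +{groups[-1]:<11} accuracy {100 * acc:5.1f}%")

print("\ntop 10 features by impurity importance:")
for name, score in ot.rank_importance(matrix, labels, top_n=10, seed=7, n_trees=100):
    print(f"  {name:<22} {score:.4f}")
# Planted driver genes, dominant signature contexts and copy-shifted genes
# should dominate this list.
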