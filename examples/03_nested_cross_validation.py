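"""Nested cross-validation of the MLP + random-forest soft-voting ensemble.

The inner folds choose the feature count, the outer folds measure accuracy
on samples never touched by standardization, selection or training.
Runs at a reduced scale (5 outer / 3 inner folds, small MLP) to finish in
about a minute.
"""

import oncotyper as ot

config = ot.default_config("tiny")
variants, cnv, labels, _ = ot.simulate_cohort(config)
matrix = ot.assemble_matrix(variants, cnv, labels, ot.schema_for(config))

mlp = ot.MlpConfig(hidden_layers=2, units_per_layer=64, learning_rate=1e-3,
                   batch_size=32, max_epochs=50, seed=0)
report = ot.nested_cv(
    matrix, labels,
    methods=("lsvc",),
    k_grid=[20, 40],
    seed=7, n_outer=5, n_inner=3,
    mlp_config=mlp, rf_config=ot.RandomForestConfig(n_trees=100),
)

print(f"ensemble accuracy : {100 * report.accuracy('ensemble'):.1f}%")
print(f"mlp accuracy      : {100 * report.accuracy('mlp'):.1f}%")
print(f"random forest     : {100 * report.accuracy('random_forest'):.1f}%")
print("\nper-fold inner-loop choices (selector, feature count):")
for fc in report.fold_choices:
    print(f"  fold {fc['fold']}: {fc['method']}, k={fc['k']} "
          f"(|selected|={fc['n_selected']})")
print("\nper-class metrics (percent):")
print(report.metrics("ensemble").round(2))
# 'accuracy' per class is the fold-averaged within-class recall; the Total
# row carries macro averages and the pooled overall accuracy.
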