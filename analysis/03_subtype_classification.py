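#!/usr/bin/env python
"""Train and apply the expression-based subtype predictor.

Silhouette-filters the labeled reference samples to the representative
core, trains the gene-selected nearest-centroid predictor with stratified
5-fold cross-validation, applies it to the whole cohort, and fits the
linear (highest-probability) phenotype classifier as the second route.
"""

from pathlib import Path

import pandas as pd

from repclonity import classifiers, io

SIM = Path("results/sim")
OUT = Path("results")
SEED = 2019

expr = io.read_expression_matrix(SIM / "expr.tsv")
labels = pd.read_csv(SIM / "labels.tsv", sep="\t", index_col=0).iloc[:, 0]

kept = classifiers.filter_training_samples(expr, labels)
print(f"silhouette filter: {len(kept)} of {expr.shape[1]} samples retained "
      "(positive width)")

model = classifiers.train_nearest_centroid(
    expr[kept], labels.loc[kept], n_genes=60, cv_folds=5, seed=SEED)
model.to_json(OUT / "centroid_model.json")
print(f"nearest-centroid predictor: {len(model.selected_genes)} genes, "
      f"cv error {100 * model.cv_error:.1f}%, "
      f"training error {100 * model.training_error:.1f}%")

calls, probs = classifiers.predict_nearest_centroid(model, expr)
pd.concat([calls, probs], axis=1).to_csv(OUT / "subtype_calls.tsv", sep="\t",
                                         index_label="sample_id")
agree = (calls.loc[labels.index] == labels).mean()
print(f"whole-cohort calls agree with generating labels for "
      f"{100 * agree:.1f}% of samples -> {OUT / 'subtype_calls.tsv'}")

# second route: variance filter + linear classifier, call = max probability
genes = classifiers.variance_filter_genes(expr, sd_threshold=0.2)
linear = classifiers.train_linear_classifier(expr.loc[genes].loc[:, kept],
                                             labels.loc[kept])
lin_calls, _ = classifiers.predict_linear(linear, expr.loc[genes])
lin_agree = (lin_calls.loc[labels.index] == labels).mean()
print(f"linear classifier ({len(genes)} genes passing sd>0.2): "
      f"{100 * lin_agree:.1f}% agreement")
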