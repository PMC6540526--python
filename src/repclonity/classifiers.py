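"""Expression-based subtype and B-cell phenotype classifiers.

Two predictors operate on genes × samples matrices of log2 expression:

* a nearest-centroid subtype predictor with per-class gene selection
  (standardized mean-difference scores with SD shrinkage, class-balanced
  allocation) trained on samples pre-filtered to positive silhouette width
  — the route used to extend a reference cohort's molecular subtypes to a
  full cohort;
* a regularized linear multiclass classifier (one linear score per class,
  softmax probabilities, call = highest probability) trained on reference
  phenotype panels, optionally after a per-gene variance filter.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import softmax
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import silhouette_samples
from sklearn.model_selection import StratifiedKFold

from ._errors import RepclonityError

__all__ = [
    "CentroidModel", "LinearClassifierModel", "silhouette_widths",
    "filter_training_samples", "train_nearest_centroid",
    "predict_nearest_centroid", "variance_filter_genes",
    "train_linear_classifier", "predict_linear",
]


def _validate_expression(X: pd.DataFrame) -> None:
    if X.index.duplicated().any():
        raise RepclonityError("expression matrix has duplicate gene identifiers")
    if not np.isfinite(X.to_numpy()).all():
        raise RepclonityError("expression matrix contains non-finite values")


def _sample_matrix(X: pd.DataFrame, distance: str) -> np.ndarray:
    """Samples × genes array, genes median-centered for the euclidean default."""
    if distance == "euclidean":
        X = X.sub(X.median(axis=1), axis=0)
    return X.to_numpy().T


def silhouette_widths(X: pd.DataFrame, labels: pd.Series,
                      distance: str = "euclidean") -> pd.Series:
    """Classic silhouette width s(i) = (b − a) / max(a, b) per sample.

    a is the mean distance to the sample's own class, b the smallest mean
    distance to any other class. All-identical samples get width 0 by the
    a = b = 0 convention.
    """
    _validate_expression(X)
    labels = pd.Series(labels).loc[X.columns]
    counts = labels.value_counts()
    if len(counts) < 2:
        raise RepclonityError("silhouette requires at least two classes")
    singletons = counts[counts < 2]
    if len(singletons):
        raise RepclonityError(
            f"singleton class(es) for silhouette: {sorted(singletons.index)}")
    metric = "euclidean" if distance == "euclidean" else "correlation"
    widths = silhouette_samples(_sample_matrix(X, distance), labels.to_numpy(),
                                metric=metric)
    return pd.Series(widths, index=X.columns, name="silhouette_width")


def filter_training_samples(X: pd.DataFrame, labels: pd.Series,
                            distance: str = "euclidean") -> list[str]:
    """Samples with strictly positive silhouette width — the subset treated
    as most representative of its class for predictor training."""
    widths = silhouette_widths(X, labels, distance=distance)
    retained = list(widths.index[widths > 0])
    kept_classes = set(pd.Series(labels).loc[retained])
    lost = set(pd.Series(labels).loc[X.columns]) - kept_classes
    if lost:
        raise RepclonityError(
            f"class(es) lost all samples in silhouette filtering: {sorted(lost)}")
    return retained


@dataclass
class CentroidModel:
    """Nearest-centroid predictor: selected genes, per-class centroids on
    those genes, the distance metric, and its error estimates."""

    selected_genes: list[str]
    classes: list[str]
    centroids: pd.DataFrame  # selected_genes × classes
    gene_medians: pd.Series  # training medians of selected genes
    distance: str
    cv_error: float
    training_error: float

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "model": "nearest_centroid",
            "selected_genes": self.selected_genes,
            "classes": self.classes,
            "centroids": {c: self.centroids[c].tolist() for c in self.classes},
            "gene_medians": self.gene_medians.tolist(),
            "distance": self.distance,
            "cv_error": self.cv_error,
            "training_error": self.training_error,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "CentroidModel":
        with open(path) as fh:
            payload = json.load(fh)
        genes = payload["selected_genes"]
        centroids = pd.DataFrame(
            {c: payload["centroids"][c] for c in payload["classes"]}, index=genes)
        return cls(selected_genes=genes, classes=payload["classes"],
                   centroids=centroids,
                   gene_medians=pd.Series(payload["gene_medians"], index=genes),
                   distance=payload["distance"], cv_error=payload["cv_error"],
                   training_error=payload["training_error"])


def _centroid_gene_scores(X: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Standardized mean-difference score per gene and class.

    score(g, k) = (mean_k − mean_not_k) / (s_pooled + s0) with s_pooled the
    pooled within-class SD and shrinkage s0 = median of pooled SDs across
    genes (keeps low-variance genes from dominating).
    """
    classes = sorted(labels.unique())
    values = X.to_numpy()
    n = values.shape[1]
    ss_within = np.zeros(values.shape[0])
    class_means = {}
    for k in classes:
        idx = (labels == k).to_numpy()
        sub = values[:, idx]
        mu = sub.mean(axis=1)
        class_means[k] = mu
        ss_within += ((sub - mu[:, None]) ** 2).sum(axis=1)
    pooled_sd = np.sqrt(ss_within / max(n - len(classes), 1))
    s0 = np.median(pooled_sd)
    scores = {}
    for k in classes:
        idx = (labels == k).to_numpy()
        out_mean = values[:, ~idx].mean(axis=1)
        scores[k] = (class_means[k] - out_mean) / (pooled_sd + s0)
    return pd.DataFrame(scores, index=X.index)


def _select_genes_balanced(scores: pd.DataFrame, n_genes: int) -> list[str]:
    """Pick n_genes with largest |score|, allocated equally across classes
    (round-robin; a gene already taken for one class is skipped)."""
    classes = list(scores.columns)
    per_class = {k: scores[k].abs().sort_values(ascending=False).index.tolist()
                 for k in classes}
    chosen: list[str] = []
    taken: set[str] = set()
    pointers = {k: 0 for k in classes}
    while len(chosen) < n_genes:
        progressed = False
        for k in classes:
            if len(chosen) >= n_genes:
                break
            ranked = per_class[k]
            while pointers[k] < len(ranked) and ranked[pointers[k]] in taken:
                pointers[k] += 1
            if pointers[k] < len(ranked):
                gene = ranked[pointers[k]]
                chosen.append(gene)
                taken.add(gene)
                pointers[k] += 1
                progressed = True
        if not progressed:
            break
    return chosen


def _fit_centroids(X: pd.DataFrame, labels: pd.Series, n_genes: int
                   ) -> tuple[list[str], pd.DataFrame]:
    scores = _centroid_gene_scores(X, labels)
    genes = _select_genes_balanced(scores, n_genes)
    sub = X.loc[genes]
    centroids = pd.DataFrame(
        {k: sub.loc[:, (labels == k).to_numpy()].mean(axis=1)
         for k in sorted(labels.unique())})
    return genes, centroids


def train_nearest_centroid(X: pd.DataFrame, labels: pd.Series, n_genes: int,
                           cv_folds: int = 5, seed: int = 0,
                           distance: str = "euclidean") -> CentroidModel:
    """Train the gene-selected nearest-centroid predictor with stratified
    cross-validated error estimation.

    cv_error is the pooled misclassification fraction over ``cv_folds``
    stratified folds, with gene selection redone inside every fold.
    """
    _validate_expression(X)
    labels = pd.Series(labels).loc[X.columns]
    classes = sorted(labels.unique())
    if n_genes < len(classes):
        raise RepclonityError(
            f"n_genes={n_genes} is below the number of classes ({len(classes)})")
    if n_genes > X.shape[0]:
        raise RepclonityError("n_genes exceeds the number of available genes")

    genes, centroids = _fit_centroids(X, labels, n_genes)
    medians = X.loc[genes].median(axis=1)
    model = CentroidModel(selected_genes=genes, classes=classes,
                          centroids=centroids, gene_medians=medians,
                          distance=distance, cv_error=np.nan, training_error=np.nan)
    calls, _ = predict_nearest_centroid(model, X)
    model.training_error = float((calls != labels).mean())

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    errors = 0
    for train_idx, test_idx in skf.split(X.columns, labels):
        tr_cols = X.columns[train_idx]
        te_cols = X.columns[test_idx]
        fold_genes, fold_centroids = _fit_centroids(
            X[tr_cols], labels.loc[tr_cols], n_genes)
        fold_model = CentroidModel(
            selected_genes=fold_genes, classes=sorted(labels.loc[tr_cols].unique()),
            centroids=fold_centroids,
            gene_medians=X.loc[fold_genes, tr_cols].median(axis=1),
            distance=distance, cv_error=np.nan, training_error=np.nan)
        fold_calls, _ = predict_nearest_centroid(fold_model, X[te_cols])
        errors += int((fold_calls != labels.loc[te_cols]).sum())
    model.cv_error = errors / X.shape[1]
    return model


def predict_nearest_centroid(model: CentroidModel, X: pd.DataFrame
                             ) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each sample to the nearest class centroid.

    Returns (labels, probabilities); probabilities are softmax of negative
    distances; distance ties resolve to the lexicographically first class.
    """
    missing = [g for g in model.selected_genes if g not in X.index]
    if missing:
        raise RepclonityError(f"expression matrix lacks model genes: {missing[:10]}"
                              + ("..." if len(missing) > 10 else ""))
    sub = X.loc[model.selected_genes]
    if model.distance == "euclidean":
        sub = sub.sub(model.gene_medians, axis=0)
        cent = model.centroids.sub(model.gene_medians, axis=0)
        d = np.sqrt(((sub.to_numpy().T[:, None, :]
                      - cent.to_numpy().T[None, :, :]) ** 2).sum(axis=2))
    elif model.distance == "correlation":
        s = sub.to_numpy().T
        c = model.centroids.to_numpy().T
        s_c = s - s.mean(axis=1, keepdims=True)
        c_c = c - c.mean(axis=1, keepdims=True)
        num = s_c @ c_c.T
        den = (np.linalg.norm(s_c, axis=1)[:, None]
               * np.linalg.norm(c_c, axis=1)[None, :])
        with np.errstate(invalid="ignore"):
            corr = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        d = 1.0 - corr
    else:
        raise ValueError(f"unknown distance {model.distance!r}")
    probs = softmax(-d, axis=1)
    # classes are sorted, so argmin's first-hit rule is the lexicographic tie-break
    calls = [model.classes[i] for i in d.argmin(axis=1)]
    return (pd.Series(calls, index=X.columns, name="subtype"),
            pd.DataFrame(probs, index=X.columns, columns=model.classes))


def variance_filter_genes(X: pd.DataFrame, sd_threshold: float = 0.2) -> list[str]:
    """Genes whose sample SD (ddof=1) is strictly above the threshold."""
    sd = X.std(axis=1, ddof=1)
    return list(X.index[(sd > sd_threshold).to_numpy()])


@dataclass
class LinearClassifierModel:
    """Multiclass linear classifier: one (weights, bias) score per class;
    the call is the class with the highest softmax probability."""

    classes: list[str]
    genes: list[str]
    weights: np.ndarray  # classes × genes
    biases: np.ndarray  # classes
    _binary: bool = field(default=False, repr=False)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {"model": "linear", "classes": self.classes,
                   "genes": self.genes, "weights": self.weights.tolist(),
                   "biases": self.biases.tolist(), "binary": self._binary}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "LinearClassifierModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(classes=payload["classes"], genes=payload["genes"],
                   weights=np.asarray(payload["weights"]),
                   biases=np.asarray(payload["biases"]),
                   _binary=payload.get("binary", False))


def train_linear_classifier(X: pd.DataFrame, labels: pd.Series,
                            regularization: float = 1.0) -> LinearClassifierModel:
    """Fit a ridge-regularized multiclass linear decision function
    (deterministic; logistic loss, lbfgs)."""
    _validate_expression(X)
    labels = pd.Series(labels).loc[X.columns]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise RepclonityError("linear classifier requires at least two classes")
    clf = LogisticRegression(C=1.0 / regularization, solver="lbfgs",
                             max_iter=2000)
    clf.fit(X.to_numpy().T, labels.to_numpy())
    weights = clf.coef_
    biases = clf.intercept_
    binary = weights.shape[0] == 1
    if binary:
        # expand the single decision function to a per-class score pair
        weights = np.vstack([-weights[0] / 2, weights[0] / 2])
        biases = np.array([-biases[0] / 2, biases[0] / 2])
    return LinearClassifierModel(classes=[str(c) for c in clf.classes_],
                                 genes=list(X.index), weights=weights,
                                 biases=biases, _binary=binary)


def predict_linear(model: LinearClassifierModel, X: pd.DataFrame
                   ) -> tuple[pd.Series, pd.DataFrame]:
    """Per-class softmax probabilities over the linear scores; the call is
    the highest-probability class (ties lexicographic)."""
    missing = [g for g in model.genes if g not in X.index]
    if missing:
        raise RepclonityError(f"expression matrix lacks model genes: {missing[:10]}"
                              + ("..." if len(missing) > 10 else ""))
    scores = X.loc[model.genes].to_numpy().T @ model.weights.T + model.biases
    probs = softmax(scores, axis=1)
    calls = [model.classes[i] for i in scores.argmax(axis=1)]
    return (pd.Series(calls, index=X.columns, name="phenotype"),
            pd.DataFrame(probs, index=X.columns, columns=model.classes))
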