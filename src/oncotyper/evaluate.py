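"""Nested cross-validation and the downstream analyses.

The outer K-fold loop estimates generalization accuracy; within each outer
training set an inner K-fold loop picks the feature-selection method and the
number of features to keep.  Standardization, selection, and classifier
training are all fit on outer-training rows only, and a runtime leakage guard
hashes every outer-test row against the rows the fold's fitting stages saw.

Also here: per-class precision/recall/F1 tables, classifier-agreement set
algebra (inclusion-exclusion over correctly-predicted sample sets), the
cumulative feature-group ablation, and impurity-based importance ranking.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support

from .classify import (
    MlpConfig,
    RandomForestConfig,
    ensemble_predict,
    train_classifier,
)
from .features import BLOCK_NAMES, FeatureMatrix
from .io import LabelMap
from .selection import SelectionProblem, select_k

logger = logging.getLogger(__name__)

#: Method preference used to break inner-loop ties (after "smaller k wins").
METHOD_ORDER = ("lsvc", "lasso", "extra_trees")


class LeakageError(RuntimeError):
    """An outer-test row was seen by a fitting stage inside its own fold."""


def _row_hashes(X: np.ndarray) -> set[bytes]:
    return {hashlib.sha1(np.ascontiguousarray(row).tobytes()).digest() for row in X}


def _assert_no_leakage(train_X: np.ndarray, test_hashes: set[bytes], stage: str) -> None:
    overlap = _row_hashes(train_X) & test_hashes
    if overlap:
        raise LeakageError(f"{len(overlap)} outer-test rows reached the {stage} stage")


@dataclass(frozen=True)
class FoldPlan:
    """Disjoint test-index sets, one per fold, stratified by label."""

    folds: tuple[np.ndarray, ...]
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.sort(np.concatenate([f for i, f in enumerate(self.folds) if i != fold]))


def stratified_folds(y: Sequence, n_folds: int, seed: int) -> FoldPlan:
    """Deterministic stratified K-fold plan.

    Within each class the (shuffled) members are dealt one at a time to the
    currently smallest fold, so fold sizes differ by at most one, class
    proportions are preserved within rounding, and a class with fewer than
    ``n_folds`` members lands in that many distinct folds.
    """
    y = np.asarray(y)
    n = len(y)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds the {n} available samples")
    rng = np.random.default_rng(seed)
    assignments = [[] for _ in range(n_folds)]
    classes, counts = np.unique(y, return_counts=True)
    # Largest classes first so small classes land in the emptiest folds.
    for c in classes[np.argsort(-counts, kind="stable")]:
        members = rng.permutation(np.flatnonzero(y == c))
        for m in members:
            sizes = [len(a) for a in assignments]
            assignments[int(np.argmin(sizes))].append(int(m))
    folds = tuple(np.sort(np.array(a, dtype=int)) for a in assignments)
    return FoldPlan(folds=folds, seed=seed)


def harmonic_f1(precision: float, recall: float) -> float:
    """F1 = 2PR/(P+R), on whatever scale P and R share (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def class_metrics(
    y_true: Sequence,
    y_pred: Sequence,
    labels: Sequence[str],
    fold_ids: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Per-class precision/recall/F1 (percent) plus accuracy columns.

    ``accuracy`` is the per-class fold-averaged recall when ``fold_ids`` is
    supplied (mean over folds of within-fold recall, folds where the class is
    absent skipped), else it equals pooled recall.  The ``Total`` row carries
    macro averages of the per-class columns and the pooled overall accuracy
    in the ``accuracy`` column.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred length mismatch")
    labels = list(labels)
    unknown = set(y_true) | set(y_pred)
    unknown -= set(labels)
    if unknown:
        raise ValueError(f"labels outside the declared label set: {sorted(unknown)[:5]}")

    p, r, f, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    rows = {
        "precision": p * 100.0,
        "recall": r * 100.0,
        "f1": np.array([harmonic_f1(pi, ri) for pi, ri in zip(p * 100, r * 100)]),
    }
    if fold_ids is not None:
        fold_ids = np.asarray(fold_ids)
        acc = []
        for c in labels:
            per_fold = []
            for fid in np.unique(fold_ids):
                in_fold = (fold_ids == fid) & (y_true == c)
                if in_fold.any():
                    per_fold.append(float(np.mean(y_pred[in_fold] == c)))
            acc.append(100.0 * float(np.mean(per_fold)) if per_fold else 0.0)
        rows["accuracy"] = np.array(acc)
    else:
        rows["accuracy"] = rows["recall"].copy()

    table = pd.DataFrame(rows, index=labels)
    overall = 100.0 * float(np.mean(y_true == y_pred))
    table.loc["Total"] = [
        table["precision"].mean(),
        table["recall"].mean(),
        table["f1"].mean(),  # macro F1 = mean of per-class F1
        overall,
    ]
    return table


@dataclass(frozen=True)
class AgreementTable:
    """Set algebra over the correctly-predicted sample sets of two classifiers."""

    pct_a: float
    pct_b: float
    pct_both: float

    @property
    def pct_either(self) -> float:
        return min(self.pct_a + self.pct_b - self.pct_both, 100.0)

    @property
    def pct_only_a(self) -> float:
        return max(self.pct_a - self.pct_both, 0.0)

    @property
    def pct_only_b(self) -> float:
        return max(self.pct_b - self.pct_both, 0.0)

    def as_row(self, decimals: int = 2) -> dict[str, float]:
        return {
            "A": round(self.pct_a, decimals),
            "B": round(self.pct_b, decimals),
            "A&B": round(self.pct_both, decimals),
            "A|B": round(self.pct_either, decimals),
            "A-B": round(self.pct_only_a, decimals),
            "B-A": round(self.pct_only_b, decimals),
        }


def agreement_table(correct_a: Sequence[bool], correct_b: Sequence[bool]) -> AgreementTable:
    """Percentages of samples each classifier (and both) predicted correctly."""
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("correct_a and correct_b must be equal-length 1-d vectors")
    if len(a) == 0:
        raise ValueError("agreement requires at least one evaluated sample")
    n = len(a)
    return AgreementTable(
        pct_a=100.0 * a.sum() / n,
        pct_b=100.0 * b.sum() / n,
        pct_both=100.0 * (a & b).sum() / n,
    )


@dataclass
class CVReport:
    """Everything nested CV produced: fold choices, predictions, metrics."""

    classes: tuple[str, ...]
    samples: tuple[str, ...]
    y_true: np.ndarray
    fold_ids: np.ndarray  # outer-fold id per sample
    predictions: dict[str, np.ndarray]  # classifier name -> predicted labels
    probabilities: dict[str, np.ndarray]  # classifier name -> (n, k) rows
    fold_choices: list[dict]  # per fold: method, k, regularization, inner table
    metadata: dict = field(default_factory=dict)

    def accuracy(self, name: str = "ensemble") -> float:
        return float(np.mean(self.predictions[name] == self.y_true))

    def correct(self, name: str) -> np.ndarray:
        return self.predictions[name] == self.y_true

    def metrics(self, name: str = "ensemble") -> pd.DataFrame:
        return class_metrics(self.y_true, self.predictions[name], self.classes, self.fold_ids)

    def agreement(self, name_a: str, name_b: str) -> AgreementTable:
        return agreement_table(self.correct(name_a), self.correct(name_b))


def inner_select_config(
    X_train: np.ndarray,
    y_train: np.ndarray,
    methods: Sequence[str],
    k_grid: Sequence[int],
    inner_plan: FoldPlan,
    seed: int = 0,
    mlp_config: Optional[MlpConfig] = None,
    rf_config: Optional[RandomForestConfig] = None,
    tolerance_frac: float = 0.05,
    select_n_trees: int = 100,
) -> tuple[str, int, pd.DataFrame]:
    """Pick (selection method, feature count) by mean inner-fold ensemble accuracy.

    Ties resolve to the smaller k, then to the method order lsvc, lasso,
    extra_trees.  With a single candidate the inner loop is skipped.
    """
    combos = [(m, int(k)) for m in methods for k in k_grid]
    if not combos:
        raise ValueError("empty (method, k) grid")
    for m, k in combos:
        if k > X_train.shape[1]:
            raise ValueError(f"k={k} exceeds the {X_train.shape[1]} available features")
    if len(combos) == 1:
        m, k = combos[0]
        table = pd.DataFrame({"method": [m], "k": [k], "mean_accuracy": [np.nan]})
        return m, k, table

    scores: dict[tuple[str, int], list[float]] = {c: [] for c in combos}
    for fold in range(inner_plan.n_folds):
        tr = inner_plan.train_indices(fold)
        va = inner_plan.folds[fold]
        problem = SelectionProblem(X_train[tr], y_train[tr])
        X_va_std = problem.transform(X_train[va])
        for m, k in combos:
            sel = select_k(
                m, problem, k, tolerance_frac=tolerance_frac, seed=seed, n_trees=select_n_trees
            )
            cols = sel.selected
            Xtr_fit = problem.X_std[:, cols] if m != "extra_trees" else problem.X[:, cols]
            Xva_fit = X_va_std[:, cols] if m != "extra_trees" else X_train[va][:, cols]
            a = train_classifier("mlp", Xtr_fit, y_train[tr], hyper=mlp_config, seed=seed)
            b = train_classifier("random_forest", Xtr_fit, y_train[tr], hyper=rf_config, seed=seed)
            labels, _ = ensemble_predict(
                a.predict_proba(Xva_fit), b.predict_proba(Xva_fit), classes=a.classes
            )
            scores[(m, k)].append(float(np.mean(labels == y_train[va])))

    rows = [
        {"method": m, "k": k, "mean_accuracy": float(np.mean(v))}
        for (m, k), v in scores.items()
    ]
    table = pd.DataFrame(rows)
    best = max(
        scores,
        key=lambda c: (np.mean(scores[c]), -c[1], -METHOD_ORDER.index(c[0])),
    )
    return best[0], best[1], table


def nested_cv(
    matrix: FeatureMatrix,
    labels: LabelMap,
    methods: Sequence[str] = ("lsvc",),
    k_grid: Optional[Sequence[int]] = None,
    seed: int = 0,
    n_outer: int = 10,
    n_inner: int = 10,
    mlp_config: Optional[MlpConfig] = None,
    rf_config: Optional[RandomForestConfig] = None,
    tolerance_frac: float = 0.05,
    extra_members: Sequence[str] = (),
    select_n_trees: int = 100,
) -> CVReport:
    """Nested K-fold evaluation of the soft-voting ensemble.

    ``k_grid`` defaults to 5/10/15/20% of the feature dimension.
    ``extra_members`` may add "ovr_svm" and/or "knn" side classifiers trained
    on the same selected features (for agreement analysis); they never enter
    the ensemble.
    """
    y = np.array([labels.mapping[s] for s in matrix.samples])
    d = matrix.schema.dimension
    if k_grid is None:
        k_grid = sorted({max(1, int(round(f * d))) for f in (0.05, 0.10, 0.15, 0.20)})
    plan = stratified_folds(y, n_outer, seed)
    classes = tuple(sorted(set(y)))
    n = len(y)

    member_names = ["mlp", "random_forest"] + list(extra_members)
    preds = {name: np.empty(n, dtype=object) for name in member_names + ["ensemble"]}
    probs = {name: np.zeros((n, len(classes))) for name in member_names + ["ensemble"]}
    fold_ids = np.empty(n, dtype=int)
    fold_choices: list[dict] = []

    for fold in range(plan.n_folds):
        tr = plan.train_indices(fold)
        te = plan.folds[fold]
        fold_ids[te] = fold
        X_tr, y_tr = matrix.values[tr], y[tr]
        X_te = matrix.values[te]
        test_hashes = _row_hashes(X_te)

        inner_plan = stratified_folds(y_tr, min(n_inner, len(tr)), seed + 1000 + fold)
        method, k, inner_table = inner_select_config(
            X_tr,
            y_tr,
            methods,
            k_grid,
            inner_plan,
            seed=seed,
            mlp_config=mlp_config,
            rf_config=rf_config,
            tolerance_frac=tolerance_frac,
            select_n_trees=select_n_trees,
        )

        _assert_no_leakage(X_tr, test_hashes, "standardization/selection")
        problem = SelectionProblem(X_tr, y_tr)
        sel = select_k(
            method, problem, k, tolerance_frac=tolerance_frac, seed=seed, n_trees=select_n_trees
        )
        cols = sel.selected
        if method == "extra_trees":
            X_fit, X_eval = X_tr[:, cols], X_te[:, cols]
        else:
            X_fit, X_eval = problem.X_std[:, cols], problem.transform(X_te)[:, cols]
        _assert_no_leakage(X_fit, test_hashes, "classifier training")

        fitted = {}
        fitted["mlp"] = train_classifier("mlp", X_fit, y_tr, hyper=mlp_config, seed=seed)
        fitted["random_forest"] = train_classifier(
            "random_forest", X_fit, y_tr, hyper=rf_config, seed=seed
        )
        for extra in extra_members:
            fitted[extra] = train_classifier(extra, X_fit, y_tr, seed=seed)

        member_probs = {name: clf.predict_proba(X_eval) for name, clf in fitted.items()}
        ens_labels, ens_probs = ensemble_predict(
            member_probs["mlp"],
            member_probs["random_forest"],
            classes=fitted["mlp"].classes,
        )
        for name in member_names:
            preds[name][te] = fitted[name].classes[np.argmax(member_probs[name], axis=1)]
            probs[name][te] = member_probs[name]
        preds["ensemble"][te] = ens_labels
        probs["ensemble"][te] = ens_probs
        fold_choices.append(
            {
                "fold": fold,
                "method": method,
                "k": k,
                "n_selected": int(sel.n_selected),
                "regularization_used": sel.regularization_used,
                "inner_table": inner_table,
            }
        )
        logger.info("outer fold %d: method=%s k=%d (|selected|=%d)", fold, method, k, sel.n_selected)

    return CVReport(
        classes=classes,
        samples=matrix.samples,
        y_true=y,
        fold_ids=fold_ids,
        predictions={k_: v.astype(str) for k_, v in preds.items()},
        probabilities=probs,
        fold_choices=fold_choices,
        metadata={
            "seed": seed,
            "methods": tuple(methods),
            "k_grid": tuple(int(k_) for k_ in k_grid),
            "n_outer": n_outer,
            "n_inner": n_inner,
        },
    )


def ablation_study(
    matrix: FeatureMatrix,
    labels: LabelMap,
    group_order: Optional[Sequence[str]] = None,
    seed: int = 0,
    n_folds: int = 10,
    n_trees: int = 300,
) -> list[tuple[tuple[str, ...], float]]:
    """Random-forest CV accuracy as feature groups are added cumulatively.

    Default order: profile, rates, spectra, scna, signatures.  Returns one
    (prefix, accuracy) pair per cumulative prefix.
    """
    order = tuple(group_order) if group_order is not None else ("profile", "rates", "spectra", "scna", "signatures")
    for g in order:
        if g not in BLOCK_NAMES:
            raise ValueError(f"unknown feature group {g!r}; expected one of {BLOCK_NAMES}")
    y = np.array([labels.mapping[s] for s in matrix.samples])
    plan = stratified_folds(y, n_folds, seed)
    results = []
    for prefix_len in range(1, len(order) + 1):
        prefix = order[:prefix_len]
        X = np.hstack([matrix.block(g) for g in prefix])
        correct = 0
        for fold in range(plan.n_folds):
            tr, te = plan.train_indices(fold), plan.folds[fold]
            clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
            clf.fit(X[tr], y[tr])
            correct += int(np.sum(clf.predict(X[te]) == y[te]))
        results.append((prefix, correct / len(y)))
    return results


def rank_importance(
    matrix: FeatureMatrix,
    labels: LabelMap,
    top_n: int = 10,
    seed: int = 0,
    n_trees: int = 300,
) -> list[tuple[str, float]]:
    """Top features by random-forest impurity importance, descending."""
    if top_n > matrix.schema.dimension:
        raise ValueError("top_n exceeds the feature dimension")
    y = np.array([labels.mapping[s] for s in matrix.samples])
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    clf.fit(matrix.values, y)
    imp = clf.feature_importances_
    order = np.lexsort((np.arange(len(imp)), -imp))[:top_n]
    cols = matrix.schema.columns
    return [(cols[i], float(imp[i])) for i in order]


def filter_by_class_size(
    matrix: FeatureMatrix, labels: LabelMap, min_samples: int
) -> tuple[FeatureMatrix, LabelMap]:
    """Drop classes with fewer than ``min_samples`` samples (and their rows)."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    y = {s: labels.mapping[s] for s in matrix.samples}
    counts: dict[str, int] = {}
    for lab in y.values():
        counts[lab] = counts.get(lab, 0) + 1
    keep_classes = {c for c, n in counts.items() if n >= min_samples}
    if len(keep_classes) == 0:
        raise ValueError(f"no class has {min_samples} or more samples")
    if len(keep_classes) < 2:
        raise ValueError(
            f"only {len(keep_classes)} class meets min_samples={min_samples}; "
            "classification needs at least two"
        )
    keep_samples = [s for s in matrix.samples if y[s] in keep_classes]
    return matrix.subset_samples(keep_samples), labels.subset(keep_samples)
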