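"""Supervised feature selection: extra-trees importance, LASSO, and an
L1-penalized squared-hinge linear classifier (LSVC), plus a controller that
drives the regularization strength to hit a requested feature count.

The L1 methods operate on standardized features (zero mean, unit variance,
statistics learned from the training rows only); the tree-based selector uses
raw values.  The LSVC sparsity budget ``sum_c ||w_c||_1 <= eps`` is
implemented in its equivalent penalized (Lagrangian) form with an inverse
penalty weight ``C``: larger ``C`` means a looser budget and more surviving
features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

METHODS = ("extra_trees", "lasso", "lsvc")


@dataclass
class SelectionProblem:
    """A labeled training matrix plus its standardization state.

    The scaler is fit on the rows given here; apply :meth:`transform` to
    held-out rows so they are standardized with training statistics only.
    """

    X: np.ndarray
    y: np.ndarray
    scaler: Optional[StandardScaler] = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if len(self.y) != self.X.shape[0]:
            raise ValueError("X and y length mismatch")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values")
        self.classes = np.unique(self.y)
        if len(self.classes) < 2:
            raise ValueError("at least two classes are required for supervised selection")
        if self.scaler is None:
            self.scaler = StandardScaler()
            self.scaler.fit(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def X_std(self) -> np.ndarray:
        return self.scaler.transform(self.X)

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        """Standardize held-out rows with the training statistics."""
        return self.scaler.transform(np.asarray(X_new, dtype=float))


@dataclass(frozen=True)
class LassoConfig:
    alpha: float = 1.0  # L1 weight in the (1/n)*SSE + alpha*||w||_1 objective
    max_iter: int = 3000
    tol: float = 1e-3

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


@dataclass(frozen=True)
class LsvcConfig:
    penalty: float = 1.0  # C: inverse of the L1 budget tightness
    max_iter: int = 3000
    tol: float = 1e-3

    def __post_init__(self):
        if self.penalty <= 0:
            raise ValueError("penalty must be positive")


@dataclass
class SelectionResult:
    method: str
    selected: np.ndarray  # sorted feature indices
    scores: np.ndarray  # per-feature importance or max-abs coefficient
    regularization_used: Optional[float] = None
    coefficients: Optional[np.ndarray] = None  # (k, d)
    intercepts: Optional[np.ndarray] = None
    path: list = field(default_factory=list)  # [(regularization, n_selected)] probes

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def feature_names(self, columns: Sequence[str]) -> tuple[str, ...]:
        return tuple(columns[i] for i in self.selected)


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    out = np.zeros((len(y), len(classes)))
    for j, c in enumerate(classes):
        out[y == c, j] = 1.0
    return out


def extra_trees_select(
    problem: SelectionProblem, k_features: int, n_trees: int = 100, seed: int = 0
) -> SelectionResult:
    """Top-k features by mean impurity-decrease importance of an extra-trees forest."""
    if not 1 <= k_features <= problem.n_features:
        raise ValueError(f"k_features must be in [1, {problem.n_features}], got {k_features}")
    forest = ExtraTreesClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(problem.X, problem.y)
    scores = forest.feature_importances_
    # Stable sort on (-importance, index): ties go to the lower index.
    order = np.lexsort((np.arange(len(scores)), -scores))
    selected = np.sort(order[:k_features])
    return SelectionResult(method="extra_trees", selected=selected, scores=scores)


def lasso_select(problem: SelectionProblem, config: LassoConfig) -> SelectionResult:
    """LASSO selection: minimize (1/n)*sum ||y_i - w^T x_i||^2 + alpha*||w||_1.

    Multiclass labels are one-hot encoded and one regression is solved per
    class; a feature is selected when any class gives it a nonzero weight.
    """
    Y = _one_hot(problem.y, problem.classes)
    X = problem.X_std
    if config.alpha == 0:
        model = LinearRegression()
        model.fit(X, Y)
        coef = np.atleast_2d(model.coef_)
        intercepts = np.atleast_1d(model.intercept_)
    else:
        # scikit-learn's lasso objective is (1/(2n))*SSE + a*||w||_1, so the
        # (1/n)-scaled objective above corresponds to a = alpha / 2.
        model = Lasso(alpha=config.alpha / 2.0, max_iter=config.max_iter, tol=config.tol)
        model.fit(X, Y)
        coef = np.atleast_2d(model.coef_)
        intercepts = np.atleast_1d(model.intercept_)
    scores = np.abs(coef).max(axis=0)
    selected = np.flatnonzero(scores != 0.0)
    return SelectionResult(
        method="lasso",
        selected=selected,
        scores=scores,
        regularization_used=config.alpha,
        coefficients=coef,
        intercepts=intercepts,
    )


def lsvc_select(problem: SelectionProblem, config: LsvcConfig, seed: int = 0) -> SelectionResult:
    """L1-penalized squared-hinge one-vs-rest linear classifier selection."""
    X = problem.X_std
    model = LinearSVC(
        penalty="l1",
        loss="squared_hinge",
        dual=False,
        C=config.penalty,
        max_iter=config.max_iter,
        tol=config.tol,
        random_state=seed,
    )
    model.fit(X, problem.y)
    coef = np.atleast_2d(model.coef_)
    intercepts = np.atleast_1d(model.intercept_)
    if coef.shape[0] == 1 and len(problem.classes) == 2:
        # liblinear fits a single margin for binary problems (positive class
        # = classes_[1]); expand to the minimal-penalty (k, d) representation.
        coef = np.vstack([np.zeros_like(coef[0]), coef[0]])
        intercepts = np.array([0.0, intercepts[0]])
    scores = np.abs(coef).max(axis=0)
    selected = np.flatnonzero(scores != 0.0)
    return SelectionResult(
        method="lsvc",
        selected=selected,
        scores=scores,
        regularization_used=config.penalty,
        coefficients=coef,
        intercepts=intercepts,
    )


def lsvc_objective(
    weights: np.ndarray,
    intercepts: np.ndarray,
    problem: SelectionProblem,
    penalty: float,
) -> float:
    """Mean multiclass squared-hinge loss plus the L1 term, as a pure function.

    The loss for a sample is ``sum_{c != y} max(0, 1 + f_c(x) - f_y(x))^2``
    with ``f_c(x) = w_c^T x + b_c``; the penalized objective adds
    ``(1/penalty) * sum_c ||w_c||_1`` (the Lagrangian counterpart of the
    budget constraint).
    """
    weights = np.asarray(weights, dtype=float)
    intercepts = np.asarray(intercepts, dtype=float)
    k = len(problem.classes)
    if weights.shape != (k, problem.n_features):
        raise ValueError(
            f"weights shape {weights.shape} does not match (k={k}, d={problem.n_features})"
        )
    if intercepts.shape != (k,):
        raise ValueError(f"intercepts shape {intercepts.shape} does not match k={k}")
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    f = problem.X_std @ weights.T + intercepts  # (n, k)
    class_index = {c: j for j, c in enumerate(problem.classes)}
    y_idx = np.array([class_index[v] for v in problem.y])
    f_true = f[np.arange(len(y_idx)), y_idx]
    margins = np.maximum(0.0, 1.0 + f - f_true[:, None])
    margins[np.arange(len(y_idx)), y_idx] = 0.0
    loss = float(np.mean(np.sum(margins**2, axis=1)))
    return loss + float(np.abs(weights).sum()) / penalty


def _fit_at(method: str, problem: SelectionProblem, reg: float, seed: int) -> SelectionResult:
    if method == "lasso":
        return lasso_select(problem, LassoConfig(alpha=reg))
    return lsvc_select(problem, LsvcConfig(penalty=reg), seed=seed)


def select_k(
    method: str,
    problem: SelectionProblem,
    k_features: int,
    tolerance_frac: float = 0.05,
    seed: int = 0,
    n_trees: int = 100,
    max_bisect: int = 40,
) -> SelectionResult:
    """Select approximately ``k_features`` features with the requested method.

    extra_trees returns the exact top-k by importance.  For the L1 methods the
    regularization is bisected on a log grid (bracket 1e-4 .. 1e4 in the
    solver's parameterization) until the surviving-feature count falls within
    ``k*(1 +/- tolerance_frac)``; if the band is never hit, the closest probe
    with at least k survivors is truncated to exactly k by |score|
    (ties to the lower index).
    """
    d = problem.n_features
    if method not in METHODS:
        raise ValueError(f"unknown selection method {method!r}; expected one of {METHODS}")
    if not 1 <= k_features <= d:
        raise ValueError(f"k_features must be in [1, {d}], got {k_features}")
    if method == "extra_trees":
        return extra_trees_select(problem, k_features, n_trees=n_trees, seed=seed)

    lo, hi = 1e-4, 1e4  # solver parameterization: alpha for lasso, C for lsvc
    weakest = lo if method == "lasso" else hi
    if k_features == d:
        res = _fit_at(method, problem, weakest, seed)
        res.selected = np.arange(d)
        res.regularization_used = weakest
        res.path.append((weakest, d))
        return res

    lo_band = int(np.floor(k_features * (1.0 - tolerance_frac)))
    hi_band = int(np.ceil(k_features * (1.0 + tolerance_frac)))
    path: list[tuple[float, int]] = []
    best_over: Optional[SelectionResult] = None  # smallest count >= k seen
    best_any: Optional[SelectionResult] = None  # largest count seen
    result = None
    for _ in range(max_bisect):
        mid = float(np.sqrt(lo * hi))
        res = _fit_at(method, problem, mid, seed)
        count = res.n_selected
        path.append((mid, count))
        if count >= k_features and (best_over is None or count < best_over.n_selected):
            best_over = res
        if best_any is None or count > best_any.n_selected:
            best_any = res
        if lo_band <= count <= hi_band and count >= 1:
            result = res
            break
        too_many = count > hi_band
        if method == "lasso":
            lo, hi = (mid, hi) if too_many else (lo, mid)
        else:  # lsvc: larger C keeps more features
            lo, hi = (lo, mid) if too_many else (mid, hi)
        if hi / lo < 1.0 + 1e-12:
            break

    if result is None:
        pick = best_over if best_over is not None else best_any
        if pick is None:  # max_bisect == 0 edge case
            pick = _fit_at(method, problem, weakest, seed)
            path.append((pick.regularization_used, pick.n_selected))
        if pick.n_selected > k_features:
            nz = pick.selected
            order = np.lexsort((nz, -pick.scores[nz]))
            pick.selected = np.sort(nz[order][:k_features])
        result = pick
    result.path = path
    return result
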