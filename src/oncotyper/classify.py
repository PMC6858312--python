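"""Probabilistic classifiers behind one contract, plus the soft-voting ensemble.

Four base classifiers are offered: a multilayer perceptron (ReLU hidden
layers, softmax output, cross-entropy loss, Adam, inverted dropout, early
stopping on a held-out validation split), a random forest, a linear
one-vs-rest SVM whose decision scores are softmaxed into probabilities, and
k-nearest neighbors.  Every fitted model returns per-class probability rows
that sum to one, with a class order fixed at fit time.

The ensemble averages two members' probability rows and predicts the argmax
(ties to the lowest class index).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC

KINDS = ("mlp", "random_forest", "ovr_svm", "knn")


@dataclass(frozen=True)
class MlpConfig:
    hidden_layers: int = 3
    units_per_layer: int = 2048
    dropout_rate: float = 0.4
    learning_rate: float = 1e-5
    batch_size: int = 128
    max_epochs: int = 200
    early_stop_patience: int = 10
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class RandomForestConfig:
    n_trees: int = 500


@dataclass(frozen=True)
class SvmConfig:
    C: float = 1.0
    platt: bool = False  # Platt scaling instead of softmax over decision scores
    max_iter: int = 5000


@dataclass(frozen=True)
class KnnConfig:
    k: int = 5


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _NumpyMLP:
    """Seeded multilayer perceptron trained with Adam on softmax cross-entropy.

    Hidden layers use ReLU and inverted dropout (training only).  A stratified
    validation split drives early stopping; the parameters of the best
    validation epoch are restored.  Training is fully deterministic given the
    seed, so the validation-loss trajectory is reproducible exactly.
    """

    def __init__(self, config: MlpConfig):
        self.config = config
        self.val_loss_history_: list[float] = []

    # -- internals -------------------------------------------------------
    def _init_params(self, d: int, k: int, rng: np.random.Generator):
        sizes = [d] + [self.config.units_per_layer] * self.config.hidden_layers + [k]
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def _forward(self, X: np.ndarray, rng: Optional[np.random.Generator] = None):
        """Returns (activations, pre-dropout hiddens, dropout masks, probs)."""
        drop = self.config.dropout_rate
        a = X
        acts = [a]
        masks = []
        for i in range(len(self.W) - 1):
            h = np.maximum(0.0, a @ self.W[i] + self.b[i])
            if rng is not None and drop > 0:
                mask = (rng.random(h.shape) >= drop) / (1.0 - drop)
                h = h * mask
            else:
                mask = None
            masks.append(mask)
            a = h
            acts.append(a)
        logits = a @ self.W[-1] + self.b[-1]
        return acts, masks, _softmax(logits)

    @staticmethod
    def _ce(probs: np.ndarray, y_idx: np.ndarray) -> float:
        p = np.clip(probs[np.arange(len(y_idx)), y_idx], 1e-12, None)
        return float(-np.mean(np.log(p)))

    def _split_validation(self, y_idx: np.ndarray, rng: np.random.Generator):
        frac = self.config.validation_fraction
        n = len(y_idx)
        if frac <= 0:
            return np.arange(n), np.array([], dtype=int)
        counts = np.bincount(y_idx)
        if (counts[counts > 0] < 2).any():
            raise ValueError(
                "every class needs at least 2 training samples when a validation "
                "split is requested; use stratified handling or set "
                "validation_fraction=0"
            )
        val: list[int] = []
        for c in range(len(counts)):
            members = np.flatnonzero(y_idx == c)
            if len(members) == 0:
                continue
            members = rng.permutation(members)
            n_val = max(1, int(round(frac * len(members))))
            n_val = min(n_val, len(members) - 1)  # keep >= 1 training sample per class
            val.extend(members[:n_val])
        val_idx = np.sort(np.array(val, dtype=int))
        train_idx = np.setdiff1d(np.arange(n), val_idx)
        return train_idx, val_idx

    # -- API ---------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "_NumpyMLP":
        X = np.asarray(X, dtype=float)
        self.classes_ = np.unique(y)
        class_index = {c: j for j, c in enumerate(self.classes_)}
        y_idx = np.array([class_index[v] for v in y])
        k = len(self.classes_)
        rng = np.random.default_rng(self.config.seed)
        self._init_params(X.shape[1], k, rng)

        train_idx, val_idx = self._split_validation(y_idx, rng)
        Xtr, ytr = X[train_idx], y_idx[train_idx]
        Xval, yval = X[val_idx], y_idx[val_idx]

        # Adam state
        mW = [np.zeros_like(w) for w in self.W]
        vW = [np.zeros_like(w) for w in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        lr = self.config.learning_rate
        bs = self.config.batch_size

        best_val = np.inf
        best_params = None
        patience_left = self.config.early_stop_patience
        self.val_loss_history_ = []

        for _epoch in range(self.config.max_epochs):
            order = rng.permutation(len(Xtr))
            for start in range(0, len(Xtr), bs):
                idx = order[start : start + bs]
                xb, yb = Xtr[idx], ytr[idx]
                acts, masks, probs = self._forward(xb, rng=rng)
                # backward
                delta = probs.copy()
                delta[np.arange(len(yb)), yb] -= 1.0
                delta /= len(yb)
                grads_W = [None] * len(self.W)
                grads_b = [None] * len(self.b)
                for layer in range(len(self.W) - 1, -1, -1):
                    grads_W[layer] = acts[layer].T @ delta
                    grads_b[layer] = delta.sum(axis=0)
                    if layer > 0:
                        delta = delta @ self.W[layer].T
                        delta *= acts[layer] > 0  # ReLU gate (post-dropout activation)
                        if masks[layer - 1] is not None:
                            delta *= masks[layer - 1]
                step += 1
                corr1 = 1.0 - beta1**step
                corr2 = 1.0 - beta2**step
                for layer in range(len(self.W)):
                    mW[layer] = beta1 * mW[layer] + (1 - beta1) * grads_W[layer]
                    vW[layer] = beta2 * vW[layer] + (1 - beta2) * grads_W[layer] ** 2
                    self.W[layer] -= lr * (mW[layer] / corr1) / (np.sqrt(vW[layer] / corr2) + eps)
                    mb[layer] = beta1 * mb[layer] + (1 - beta1) * grads_b[layer]
                    vb[layer] = beta2 * vb[layer] + (1 - beta2) * grads_b[layer] ** 2
                    self.b[layer] -= lr * (mb[layer] / corr1) / (np.sqrt(vb[layer] / corr2) + eps)

            if len(Xval):
                _, _, val_probs = self._forward(Xval)
                val_loss = self._ce(val_probs, yval)
                self.val_loss_history_.append(val_loss)
                if val_loss < best_val - 1e-9:
                    best_val = val_loss
                    best_params = ([w.copy() for w in self.W], [b.copy() for b in self.b])
                    patience_left = self.config.early_stop_patience
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        break

        if best_params is not None:
            self.W, self.b = best_params
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.zeros((0, len(self.classes_)))
        _, _, probs = self._forward(X)
        return probs


@dataclass
class ProbabilisticClassifier:
    """Uniform fitted-model contract: per-class probability rows, fixed class order."""

    kind: str
    model: object
    classes: np.ndarray
    n_features: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got matrix of shape {X.shape}"
            )
        if X.shape[0] == 0:
            return np.zeros((0, len(self.classes)))
        if self.kind == "ovr_svm":
            if hasattr(self.model, "predict_proba"):  # Platt-calibrated variant
                return self.model.predict_proba(X)
            scores = self.model.decision_function(X)
            if scores.ndim == 1:  # binary: liblinear returns one margin
                scores = np.column_stack([-scores, scores])
            return _softmax(scores)
        return self.model.predict_proba(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.predict_proba(X), axis=1)]


def train_classifier(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    hyper=None,
    seed: int = 0,
) -> ProbabilisticClassifier:
    """Fit one of the four base classifiers.

    ``hyper`` is the kind's config dataclass (``MlpConfig``,
    ``RandomForestConfig``, ``SvmConfig`` or ``KnnConfig``); defaults apply
    when omitted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    if X.shape[1] < 1:
        raise ValueError("training requires at least one feature")

    if kind == "mlp":
        base_config = hyper if hyper is not None else MlpConfig()
        config = MlpConfig(**{**base_config.__dict__, "seed": seed})
        model = _NumpyMLP(config).fit(X, y)
        return ProbabilisticClassifier("mlp", model, model.classes_, X.shape[1])
    if kind == "random_forest":
        config = hyper if hyper is not None else RandomForestConfig()
        model = RandomForestClassifier(
            n_estimators=config.n_trees, criterion="gini", random_state=seed, n_jobs=1
        ).fit(X, y)
        return ProbabilisticClassifier("random_forest", model, model.classes_, X.shape[1])
    if kind == "ovr_svm":
        config = hyper if hyper is not None else SvmConfig()
        base = LinearSVC(C=config.C, max_iter=config.max_iter, random_state=seed)
        if config.platt:
            from sklearn.calibration import CalibratedClassifierCV

            base = CalibratedClassifierCV(base, method="sigmoid", cv=3)
        model = base.fit(X, y)
        return ProbabilisticClassifier("ovr_svm", model, model.classes_, X.shape[1])
    if kind == "knn":
        config = hyper if hyper is not None else KnnConfig()
        model = KNeighborsClassifier(n_neighbors=config.k).fit(X, y)
        return ProbabilisticClassifier("knn", model, model.classes_, X.shape[1])
    raise ValueError(f"unknown classifier kind {kind!r}; expected one of {KINDS}")


def predict_proba(model: ProbabilisticClassifier, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)


def ensemble_predict(
    probs_a: np.ndarray, probs_b: np.ndarray, classes: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Soft vote: average two members' probability rows and take the argmax.

    Returns ``(labels, probs)``; labels are class indices unless ``classes``
    is given.  Ties resolve to the lowest class index.
    """
    probs_a = np.asarray(probs_a, dtype=float)
    probs_b = np.asarray(probs_b, dtype=float)
    if probs_a.shape != probs_b.shape:
        raise ValueError(f"probability shapes differ: {probs_a.shape} vs {probs_b.shape}")
    probs = (probs_a + probs_b) / 2.0
    idx = np.argmax(probs, axis=1)
    labels = classes[idx] if classes is not None else idx
    return labels, probs


@dataclass
class EnsembleModel:
    """Two probabilistic members sharing a class order; defaults: MLP + random forest."""

    member_a: ProbabilisticClassifier
    member_b: ProbabilisticClassifier

    def __post_init__(self):
        if not np.array_equal(self.member_a.classes, self.member_b.classes):
            raise ValueError("ensemble members must share the same class order")
        if self.member_a.n_features != self.member_b.n_features:
            raise ValueError("ensemble members must share the feature count")

    @property
    def classes(self) -> np.ndarray:
        return self.member_a.classes

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return ensemble_predict(self.member_a.predict_proba(X), self.member_b.predict_proba(X))[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        labels, _ = ensemble_predict(
            self.member_a.predict_proba(X), self.member_b.predict_proba(X), classes=self.classes
        )
        return labels


def train_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    mlp_config: Optional[MlpConfig] = None,
    rf_config: Optional[RandomForestConfig] = None,
    seed: int = 0,
) -> EnsembleModel:
    """Train the default MLP + random-forest soft-voting ensemble."""
    mlp_config = mlp_config if mlp_config is not None else MlpConfig(seed=seed)
    a = train_classifier("mlp", X, y, hyper=mlp_config, seed=seed)
    b = train_classifier("random_forest", X, y, hyper=rf_config, seed=seed)
    return EnsembleModel(member_a=a, member_b=b)
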