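"""Class-weighted classifiers for unbalanced heart-beat data.

Two models are provided, both giving higher misclassification cost to the
minority (pathological) classes:

* :class:`WeightedLDA` — Gaussian classes with a shared covariance, fitted
  in closed form.  The pooled covariance is the class-weighted scatter

      Sigma = sum_k c_k S_k / sum_k c_k N_k,

  where ``S_k`` is the within-class scatter and ``c_k`` the class weight;
  equal weights recover ordinary LDA exactly.  Prediction maximizes the
  linear discriminant f_k(x) = -1/2 mu_k' Sigma^-1 mu_k + mu_k' Sigma^-1 x,
  i.e. assigns the class with the smallest Mahalanobis distance to its mean.
* :class:`WeightedSVM` — a one-against-one ensemble of soft-margin SVMs
  with a polynomial kernel (x'z + 1)^d, where each pairwise problem
  penalizes slack of class k by C * c_k.  The pairwise solver is
  scikit-learn's SVC; the weighting contract, pairing scheme and
  deterministic tie-breaking live here.

Class weights default to the inverse class priors of the training split
(normalized to sum to the number of classes); for the SVM an explicit
weight dict is applied unnormalized so that weighting a class by m is
equivalent to duplicating its samples m times.  Ties are always broken
toward the lowest class index (classes are kept in sorted order).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "WeightedLDA", "WeightedSVM", "WSVMSpec",
    "fit_wlda", "predict_wlda", "fit_wsvm",
    "resolve_class_weights",
]

DEGREE_RANGE = (1, 4)
C_RANGE = (1e-5, 1e5)


def resolve_class_weights(y, classes, mode="inverse-prior", normalize=True) -> dict:
    """Per-class weights: inverse priors (normalized to sum K) or explicit.

    An explicit dict must only name classes present in ``y``; a named class
    absent from the data is an error.
    """
    classes = list(classes)
    if isinstance(mode, dict):
        for k in mode:
            if k not in classes:
                raise ValueError(f"class {k!r} has a weight but is absent from y")
        return {k: float(mode.get(k, 1.0)) for k in classes}
    if mode in (None, "uniform"):
        return {k: 1.0 for k in classes}
    if mode != "inverse-prior":
        raise ValueError(f"unknown class-weight mode {mode!r}")
    y = np.asarray(y)
    n = len(y)
    counts = {k: int(np.sum(y == k)) for k in classes}
    w = {k: n / counts[k] for k in classes}
    if normalize:
        s = sum(w.values())
        w = {k: v * len(classes) / s for k, v in w.items()}
    return w


class WeightedLDA:
    """Closed-form linear discriminant analysis with class weights."""

    def __init__(self, class_weights="inverse-prior", ridge_scale: float = 1e-8):
        self.class_weights = class_weights
        self.ridge_scale = ridge_scale

    def fit(self, X, y) -> "WeightedLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("at least 2 classes are required")
        self.weights_ = resolve_class_weights(y, self.classes_, self.class_weights)
        d = X.shape[1]
        self.means_ = np.empty((len(self.classes_), d))
        sigma = np.zeros((d, d))
        denom = 0.0
        for k, cls in enumerate(self.classes_):
            Xk = X[y == cls]
            if len(Xk) == 0:
                raise ValueError(f"class {cls!r} absent from y")
            c = self.weights_[cls]
            self.means_[k] = Xk.mean(axis=0)
            dev = Xk - self.means_[k]
            sigma += c * dev.T @ dev
            denom += c * len(Xk)
        sigma /= denom
        self.covariance_ = self._regularize(sigma)
        self._sigma_inv_means = np.linalg.solve(self.covariance_, self.means_.T).T
        return self

    def _regularize(self, sigma: np.ndarray) -> np.ndarray:
        try:
            np.linalg.cholesky(sigma)
            if np.linalg.cond(sigma) < 1e12:
                return sigma
        except np.linalg.LinAlgError:
            pass
        tr = np.trace(sigma)
        eps = self.ridge_scale * (tr / sigma.shape[0] if tr > 0 else 1.0)
        return sigma + eps * np.eye(sigma.shape[0])

    def decision_function(self, X) -> np.ndarray:
        """f_k(x) = -1/2 mu_k' Sigma^-1 mu_k + mu_k' Sigma^-1 x, per class."""
        X = np.asarray(X, dtype=float)
        a = self._sigma_inv_means  # (K, d) rows Sigma^-1 mu_k
        b = -0.5 * np.einsum("kd,kd->k", a, self.means_)
        return X @ a.T + b

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]  # first max = lowest class

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "model": "wlda", "version": 1,
            "classes": [str(c) for c in self.classes_],
            "weights": {str(k): v for k, v in self.weights_.items()},
            "means": self.means_.tolist(),
            "covariance": self.covariance_.tolist(),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "WeightedLDA":
        payload = json.loads(Path(path).read_text())
        model = cls(class_weights={k: v for k, v in payload["weights"].items()})
        model.classes_ = np.array(payload["classes"], dtype=object)
        model.weights_ = {k: float(v) for k, v in payload["weights"].items()}
        model.means_ = np.array(payload["means"])
        model.covariance_ = np.array(payload["covariance"])
        model._sigma_inv_means = np.linalg.solve(model.covariance_, model.means_.T).T
        return model


def fit_wlda(X, y, class_weights="inverse-prior") -> WeightedLDA:
    return WeightedLDA(class_weights=class_weights).fit(X, y)


def predict_wlda(model: WeightedLDA, X) -> np.ndarray:
    return model.predict(X)


@dataclass
class WSVMSpec:
    """Hyperparameters of the weighted polynomial-kernel SVM."""

    kernel_degree: int = 3
    C: float = 1.0
    class_weights: object = "inverse-prior"
    multiclass: str = "one-against-one"

    def __post_init__(self) -> None:
        if not DEGREE_RANGE[0] <= self.kernel_degree <= DEGREE_RANGE[1]:
            raise ValueError(
                f"kernel degree must lie in {DEGREE_RANGE}, got {self.kernel_degree}"
            )
        # tiny slack: logspace endpoints land one ulp outside the bound
        if not C_RANGE[0] * (1 - 1e-9) <= self.C <= C_RANGE[1] * (1 + 1e-9):
            raise ValueError(f"C must lie in {C_RANGE}, got {self.C}")
        if self.multiclass != "one-against-one":
            raise ValueError("only the one-against-one scheme is supported")


class WeightedSVM:
    """One-against-one weighted SVM with kernel (x'z + 1)^d."""

    def __init__(
        self,
        spec: WSVMSpec | None = None,
        standardize: bool = False,
        max_iter: int = -1,
        tol: float = 1e-3,
    ):
        self.spec = spec or WSVMSpec()
        self.standardize = standardize
        self.max_iter = max_iter
        self.tol = tol

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if not self.standardize:
            return X
        return (X - self._loc) / self._scale

    def fit(self, X, y) -> "WeightedSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise ValueError("SVM training requires finite feature values")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("at least 2 classes are required")
        if self.standardize:
            self._loc = X.mean(axis=0)
            scale = X.std(axis=0)
            self._scale = np.where(scale > 0, scale, 1.0)
        Xt = self._transform(X)
        mode = self.spec.class_weights
        if isinstance(mode, dict):
            weights = resolve_class_weights(y, self.classes_, mode)
        else:
            weights = resolve_class_weights(y, self.classes_, mode, normalize=True)
        self.weights_ = weights
        self.models_ = {}
        for a, b in combinations(self.classes_, 2):
            rows = (y == a) | (y == b)
            svc = SVC(
                kernel="poly", degree=self.spec.kernel_degree, C=self.spec.C,
                gamma=1.0, coef0=1.0,
                class_weight={a: weights[a], b: weights[b]},
                max_iter=self.max_iter, tol=self.tol, cache_size=256,
            )
            try:
                svc.fit(Xt[rows], y[rows])
            except Exception as exc:  # pragma: no cover - solver failure path
                raise RuntimeError(
                    f"SVM solver failed for class pair ({a!r}, {b!r}): {exc}"
                ) from exc
            self.models_[(a, b)] = svc
        return self

    def predict(self, X) -> np.ndarray:
        Xt = self._transform(np.asarray(X, dtype=float))
        idx = {c: i for i, c in enumerate(self.classes_)}
        votes = np.zeros((len(Xt), len(self.classes_)), dtype=int)
        for (a, b), svc in self.models_.items():
            pred = svc.predict(Xt)
            for cls in (a, b):
                votes[pred == cls, idx[cls]] += 1
        return self.classes_[np.argmax(votes, axis=1)]  # ties -> lowest class


def fit_wsvm(X, y, spec: WSVMSpec | None = None, **kwargs) -> WeightedSVM:
    return WeightedSVM(spec=spec, **kwargs).fit(X, y)
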