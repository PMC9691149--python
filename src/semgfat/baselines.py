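"""Multi-SVM and Multi-LDA fatigue classifiers on entropy features.

Both consume the 12-dimensional feature vector of one action cycle (PSE
and WPE of the six muscles) and predict one of the four fatigue classes.

Multi-SVM is a soft-margin kernel machine with the Gaussian kernel
``K(x, y) = exp(-||x - y||^2 / sigma^2)`` combined one-vs-one; sigma and
the penalty C are picked on the validation set by grid search when not
fixed. The quadratic-programming solver is scikit-learn's SVC; the
kernel parametrisation and model selection live here.

Multi-LDA is Fisher discriminant analysis implemented directly: the
between-class scatter S_B and within-class scatter S_W are formed from
the class means, the projection ``w`` maximising ``w^T S_B w / w^T S_W w``
is the leading eigenvectors of the generalized eigenproblem
``S_B w = eigval * S_W w`` (at most classes-1 = 3 informative directions),
and samples are assigned to the nearest class centroid in the projected
space.

Features are z-scored on training statistics before either classifier —
RBF distances and scatter matrices need comparable scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg
from sklearn.svm import SVC

__all__ = [
    "SVMConfig",
    "FeatureScaler",
    "MultiSVM",
    "LDAModel",
    "rbf_kernel",
    "train_multisvm",
    "train_multilda",
    "predict_baseline",
]


def rbf_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Gaussian similarity kernel exp(-||x-y||^2 / sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.exp(-np.sum((x - y) ** 2) / sigma ** 2))


@dataclass(frozen=True)
class SVMConfig:
    sigma: float | None = None  # None -> validation grid search
    C: float | None = None
    sigma_grid: tuple[float, ...] = tuple(np.logspace(-1, 1, 7).round(4))
    C_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    multiclass: str = "one_vs_one"

    def validate(self) -> None:
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.C is not None and self.C <= 0:
            raise ValueError("C must be positive")


@dataclass
class FeatureScaler:
    """z-score transform frozen on training statistics."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        return cls(mean=X.mean(axis=0), std=std)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.std


@dataclass
class MultiSVM:
    svc: SVC
    scaler: FeatureScaler
    sigma: float
    C: float

    @property
    def n_features(self) -> int:
        return self.scaler.mean.size

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        Xs = self.scaler.transform(X)
        labels = self.svc.predict(Xs).astype(int)
        # per-class scores: one-vs-one votes aggregated to ovr decision values
        scores = self.svc.decision_function(Xs)
        if scores.ndim == 1:  # binary fit degenerates to a single margin
            scores = np.stack([-scores, scores], axis=1)
        return labels, scores


def _fit_svc(X: np.ndarray, y: np.ndarray, sigma: float, C: float) -> SVC:
    svc = SVC(
        kernel="rbf",
        gamma=1.0 / sigma ** 2,
        C=C,
        decision_function_shape="ovr",
    )
    svc.fit(X, y)
    return svc


def train_multisvm(
    train_X: np.ndarray,
    train_y: np.ndarray,
    cfg: SVMConfig | None = None,
    val_X: np.ndarray | None = None,
    val_y: np.ndarray | None = None,
) -> MultiSVM:
    """Fit the one-vs-one Gaussian-kernel SVM.

    When sigma or C is unset, every grid combination is fitted and the
    one with the best validation accuracy wins (ties -> first in grid
    order); without a validation set the training set is reused.
    """
    cfg = cfg or SVMConfig()
    cfg.validate()
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y, dtype=int)
    if len(np.unique(train_y)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    scaler = FeatureScaler.fit(train_X)
    Xs = scaler.transform(train_X)

    sigmas = (cfg.sigma,) if cfg.sigma is not None else cfg.sigma_grid
    Cs = (cfg.C,) if cfg.C is not None else cfg.C_grid

    if val_X is None or val_y is None:
        vXs, vy = Xs, train_y
    else:
        vXs, vy = scaler.transform(val_X), np.asarray(val_y, dtype=int)

    best = None
    for sigma in sigmas:
        for C in Cs:
            svc = _fit_svc(Xs, train_y, sigma, C)
            acc = float(np.mean(svc.predict(vXs) == vy))
            if best is None or acc > best[0]:
                best = (acc, sigma, C, svc)
    _, sigma, C, svc = best
    return MultiSVM(svc=svc, scaler=scaler, sigma=sigma, C=C)


@dataclass
class LDAModel:
    SB: np.ndarray  # (d, d) between-class scatter
    SW: np.ndarray  # (d, d) within-class scatter
    w: np.ndarray  # (d, classes-1) Fisher projection
    centroids: np.ndarray  # (classes, classes-1) class means, projected
    classes: np.ndarray
    scaler: FeatureScaler
    regularized: bool = False

    @property
    def n_features(self) -> int:
        return self.SB.shape[0]

    def fisher_ratio(self, direction: np.ndarray) -> float:
        d = np.asarray(direction, dtype=float)
        denom = d @ self.SW @ d
        return float((d @ self.SB @ d) / denom)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        proj = self.scaler.transform(X) @ self.w
        d2 = ((proj[:, None, :] - self.centroids[None]) ** 2).sum(axis=2)
        labels = self.classes[np.argmin(d2, axis=1)]
        return labels, -d2  # negative distances serve as class scores


def train_multilda(
    train_X: np.ndarray, train_y: np.ndarray, shrinkage: float = 1e-8
) -> LDAModel:
    """Fisher LDA on scatter matrices with nearest-centroid classification."""
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set must contain at least 2 classes")
    scaler = FeatureScaler.fit(X)
    Xs = scaler.transform(X)

    d = Xs.shape[1]
    grand = Xs.mean(axis=0)
    SB = np.zeros((d, d))
    SW = np.zeros((d, d))
    means = []
    for c in classes:
        Xc = Xs[y == c]
        mu = Xc.mean(axis=0)
        means.append(mu)
        SB += Xc.shape[0] * np.outer(mu - grand, mu - grand)
        SW += (Xc - mu).T @ (Xc - mu)

    regularized = False
    try:
        cond = np.linalg.cond(SW)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        SW = SW + shrinkage * np.trace(SW) / d * np.eye(d)
        regularized = True

    # top classes-1 generalized eigenvectors of SB w = eigval SW w
    eigvals, eigvecs = linalg.eigh(SB, SW)
    order = np.argsort(eigvals)[::-1]
    n_dir = classes.size - 1
    w = eigvecs[:, order[:n_dir]]

    centroids = np.stack([m @ w for m in means])
    return LDAModel(
        SB=SB, SW=SW, w=w, centroids=centroids, classes=classes,
        scaler=scaler, regularized=regularized,
    )


def predict_baseline(
    classifier: MultiSVM | LDAModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and per-class decision scores from a trained baseline."""
    return classifier.predict(X)
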