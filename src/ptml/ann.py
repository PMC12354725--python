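"""Shallow neural counterparts of the linear PTML models.

Four families over the same nine-input feature table, named by the
``A:B-C(-D)-E:F`` architecture code (A inputs; hidden layer widths between;
F outputs):

* ``LNN`` — linear network, equivalent to OLS on the inputs;
* ``MLP`` — multilayer perceptron (≤ 20 units per hidden layer), trained
  with a standard gradient method to a loss-improvement tolerance;
* ``RBF`` — radial basis function network (≤ 300 centers) assembled in the
  classical three stages: k-means center assignment, k-nearest-neighbour
  width assignment, pseudo-inverse (linear least squares) output weights;
* ``GRNN`` — generalized regression network, i.e. Nadaraya–Watson kernel
  regression with one bandwidth chosen on a validation shard.

All training is a pure function of (features, targets, spec, seed).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.preprocessing import StandardScaler

from .errors import ConfigError, ValidationError
from .evaluation import MetricsReport, classification_metrics, regression_metrics

_ARCH = re.compile(r"^(\d+):(\d+(?:-\d+)*)-(\d+):(\d+)$")

MAX_MLP_UNITS = 20
MAX_RBF_CENTERS = 300


@dataclass(frozen=True)
class NetworkSpec:
    arch_code: str
    family: str  # LNN | MLP | RBF | GRNN
    task: str = "regression"
    max_iter: int = 3000
    seed: int = 0

    @property
    def n_inputs(self) -> int:
        return self._parts()[0]

    @property
    def hidden(self) -> tuple[int, ...]:
        return self._parts()[1]

    def _parts(self) -> tuple[int, tuple[int, ...], int]:
        m = _ARCH.match(self.arch_code)
        if not m:
            raise ConfigError(f"bad architecture code {self.arch_code!r}")
        a = int(m.group(1))
        middle = [int(x) for x in m.group(2).split("-")]
        f = int(m.group(4))
        if middle[0] != a:
            raise ConfigError(f"{self.arch_code!r}: input width B must equal A")
        hidden = tuple(middle[1:])
        return a, hidden, f

    def validate(self, n_features: int) -> None:
        a, hidden, _ = self._parts()
        if a != n_features:
            raise ConfigError(
                f"{self.arch_code!r}: {a} inputs but feature table has {n_features}"
            )
        if self.family == "MLP":
            if any(h > MAX_MLP_UNITS for h in hidden):
                raise ConfigError(f"MLP hidden layers limited to {MAX_MLP_UNITS} units")
            if not hidden:
                raise ConfigError("MLP needs at least one hidden layer")
        if self.family == "RBF":
            if len(hidden) != 1:
                raise ConfigError("RBF takes exactly one hidden (center) layer")
            if hidden[0] > MAX_RBF_CENTERS:
                raise ConfigError(f"RBF centers limited to {MAX_RBF_CENTERS}")
        if self.family == "LNN" and hidden:
            raise ConfigError("LNN has no hidden layer")


# ---------------------------------------------------------------------------
# RBF network
# ---------------------------------------------------------------------------

class RBFNetwork:
    """Gaussian RBF network: k-means centers, k-NN widths, least-squares
    output weights (with a bias unit)."""

    def __init__(self, centers: np.ndarray, widths: np.ndarray, weights: np.ndarray, scaler):
        self.centers = centers
        self.widths = widths
        self.weights = weights
        self._scaler = scaler

    def _phi(self, X: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        phi = np.exp(-d2 / (2.0 * self.widths[None, :] ** 2))
        return np.column_stack([np.ones(len(X)), phi])

    def predict(self, features) -> np.ndarray:
        X = self._scaler.transform(np.asarray(features, dtype=float))
        return self._phi(X) @ self.weights


def rbf_fit(
    features, targets: Sequence[float], centers: int, seed: int = 0
) -> RBFNetwork:
    """Fit an RBF regressor by the three-stage KM/KN/PI scheme."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    n = len(X)
    if centers > n:
        raise ConfigError(f"{centers} centers exceed {n} rows")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    if centers == n:
        C = Xs.copy()
    else:
        km = KMeans(n_clusters=centers, random_state=seed, n_init=10)
        km.fit(Xs)
        C = km.cluster_centers_
    # widths from distances to the k nearest other centers
    if centers == 1:
        d = np.linalg.norm(Xs - C[0], axis=1)
        widths = np.array([max(float(np.mean(d)), 1e-6)])
    else:
        dist = np.linalg.norm(C[:, None, :] - C[None, :, :], axis=2)
        np.fill_diagonal(dist, np.inf)
        k = min(2, centers - 1)
        nearest = np.sort(dist, axis=1)[:, :k]
        widths = np.maximum(nearest.mean(axis=1), 1e-6)
    net = RBFNetwork(C, widths, np.zeros(centers + 1), scaler)
    phi = net._phi(Xs)
    net.weights = np.linalg.pinv(phi) @ y
    return net


# ---------------------------------------------------------------------------
# GRNN
# ---------------------------------------------------------------------------

class GRNN:
    """Nadaraya–Watson kernel regressor with a single Gaussian bandwidth."""

    def __init__(self, X: np.ndarray, y: np.ndarray, bandwidth: float, scaler):
        self._X = X
        self._y = y
        self.bandwidth = bandwidth
        self._scaler = scaler

    def predict(self, features) -> np.ndarray:
        X = self._scaler.transform(np.asarray(features, dtype=float))
        d2 = ((X[:, None, :] - self._X[None, :, :]) ** 2).sum(axis=2)
        w = np.exp(-d2 / (2.0 * self.bandwidth**2))
        norm = w.sum(axis=1)
        out = np.where(norm > 1e-300, (w @ self._y) / np.maximum(norm, 1e-300), np.nan)
        # a query far from every stored point falls back to its nearest one
        far = ~np.isfinite(out) | (norm <= 1e-300)
        if far.any():
            nearest = d2.argmin(axis=1)
            out[far] = self._y[nearest[far]]
        return out


def grnn_fit(features, targets: Sequence[float], seed: int = 0) -> GRNN:
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    rng = np.random.default_rng(seed)
    n = len(Xs)
    idx = rng.permutation(n)
    n_val = max(1, n // 5)
    val, tr = idx[:n_val], idx[n_val:]
    if len(tr) == 0:
        tr = val
    # bandwidth grid around the median pairwise distance of a subsample
    sub = Xs[rng.choice(n, size=min(n, 200), replace=False)]
    d = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=2)
    med = float(np.median(d[d > 0])) if (d > 0).any() else 1.0
    best = None
    for factor in (0.05, 0.1, 0.2, 0.4, 0.7, 1.0, 1.5, 2.5):
        h = max(factor * med, 1e-3)
        model = GRNN(Xs[tr], y[tr], h, scaler)
        pred = model.predict(scaler.inverse_transform(Xs[val]))
        mse = float(np.mean((pred - y[val]) ** 2))
        if best is None or mse < best[0]:
            best = (mse, h)
    return GRNN(Xs, y, best[1], scaler)


# ---------------------------------------------------------------------------
# Linear network
# ---------------------------------------------------------------------------

class LNN:
    """Linear network: an affine map fitted by least squares (OLS)."""

    def __init__(self, coef: np.ndarray, intercept: float):
        self.coef = coef
        self.intercept = intercept

    def predict(self, features) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        return X @ self.coef + self.intercept


def lnn_fit(features, targets) -> LNN:
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    A = np.column_stack([np.ones(len(X)), X])
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    return LNN(beta[1:], float(beta[0]))


# ---------------------------------------------------------------------------
# Trainers
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    spec: NetworkSpec
    model: object
    metrics: dict[str, MetricsReport]
    scaler: StandardScaler | None = None

    def predict(self, features) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return np.asarray(self.model.predict(X), dtype=float)

    def predict_proba(self, features) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return self.model.predict_proba(X)


def _split_frames(features: pd.DataFrame, targets, split: Sequence[str]):
    split = np.asarray(split, dtype=object)
    y = np.asarray(targets)
    tr = split == "t"
    te = split == "v"
    if not tr.any():
        raise ConfigError("no training rows (split label 't')")
    return features.loc[tr], y[tr], features.loc[te], y[te]


def train_regressor(
    features: pd.DataFrame,
    yields: Sequence[float],
    spec: NetworkSpec,
    seed: int | None = None,
    split: Sequence[str] | None = None,
    threshold: float = 79.0,
) -> TrainedModel:
    """Train a regression network on the training rows and report R/MAE/
    RMSE (with low/high-yield stratification) for both subsets."""
    seed = spec.seed if seed is None else seed
    spec.validate(features.shape[1])
    if split is None:
        split = ["t"] * len(features)
    Xtr, ytr, Xte, yte = _split_frames(features, yields, split)

    scaler = None
    if spec.family == "MLP":
        scaler = StandardScaler().fit(Xtr.to_numpy(dtype=float))
        reg = MLPRegressor(
            hidden_layer_sizes=spec.hidden,
            random_state=seed,
            max_iter=spec.max_iter,
            tol=1e-6,
            n_iter_no_change=50,
            learning_rate_init=0.01,
        )
        reg.fit(scaler.transform(Xtr.to_numpy(dtype=float)), ytr.astype(float))
        if not np.all(np.isfinite(reg.loss_curve_)):
            raise ValidationError("divergent MLP training: non-finite loss")
        model = reg
    elif spec.family == "RBF":
        model = rbf_fit(Xtr, ytr, centers=spec.hidden[0], seed=seed)
    elif spec.family == "GRNN":
        model = grnn_fit(Xtr, ytr, seed=seed)
    elif spec.family == "LNN":
        model = lnn_fit(Xtr, ytr)
    else:
        raise ConfigError(f"unknown family {spec.family!r}")

    trained = TrainedModel(spec, model, {}, scaler)
    metrics = {"train": regression_metrics(ytr, trained.predict(Xtr), threshold, "train")}
    if len(Xte):
        metrics["test"] = regression_metrics(yte, trained.predict(Xte), threshold, "test")
    trained.metrics = metrics
    return trained


def train_classifier(
    features: pd.DataFrame,
    labels: Sequence[int],
    spec: NetworkSpec,
    seed: int | None = None,
    split: Sequence[str] | None = None,
) -> TrainedModel:
    """Train a binary MLP classifier; reports accuracy, precision, recall,
    F1, TPR/TNR, confusion matrix and rank-statistic AUC per subset."""
    seed = spec.seed if seed is None else seed
    spec.validate(features.shape[1])
    if split is None:
        split = ["t"] * len(features)
    Xtr, ytr, Xte, yte = _split_frames(features, labels, split)
    ytr = ytr.astype(int)
    if len(np.unique(ytr)) < 2:
        raise ValidationError("degenerate labels: training set has a single class")
    if spec.family != "MLP":
        raise ConfigError("classification is implemented for the MLP family")
    scaler = StandardScaler().fit(Xtr.to_numpy(dtype=float))
    clf = MLPClassifier(
        hidden_layer_sizes=spec.hidden,
        random_state=seed,
        max_iter=spec.max_iter,
        tol=1e-6,
        n_iter_no_change=50,
        learning_rate_init=0.01,
    )
    clf.fit(scaler.transform(Xtr.to_numpy(dtype=float)), ytr)
    trained = TrainedModel(spec, clf, {}, scaler)
    metrics = {
        "train": classification_metrics(ytr, trained.predict_proba(Xtr)[:, 1], subset="train")
    }
    if len(Xte):
        metrics["test"] = classification_metrics(
            yte.astype(int), trained.predict_proba(Xte)[:, 1], subset="test"
        )
    trained.metrics = metrics
    return trained


def cycle_prevalence_feature(
    reuse_cycles: Sequence[int],
    labels: Sequence[int],
    train_mask: Sequence[bool] | None = None,
) -> np.ndarray:
    """Classifier reference input: per reuse cycle, the training-population
    prevalence of class 1 (the probability of a desired outcome at that
    reusability time), broadcast to every record of that cycle."""
    cycles = np.asarray(reuse_cycles)
    y = np.asarray(labels, dtype=float)
    mask = np.ones(len(cycles), dtype=bool) if train_mask is None else np.asarray(train_mask)
    overall = float(y[mask].mean())
    prev: dict = {}
    for c in np.unique(cycles[mask]):
        prev[c] = float(y[mask & (cycles == c)].mean())
    return np.array([prev.get(c, overall) for c in cycles])
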