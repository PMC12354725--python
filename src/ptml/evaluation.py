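"""Splitting, binarization, metric suites and feature importance.

The train/validation split mirrors the stratified deterministic procedure
used to build the published models: sort by reaction type and descending
yield, then send every fourth record (positions 4, 8, 12, ... of the
1-based sorted order) to validation — roughly 75/25 with each reaction
type's share preserved.

Yield binarization splits reactions into desired (> threshold → 1) and
undesirable (≤ threshold → 0); the published threshold, 79%, is the mean
yield of the source dataset, so the default threshold here is the mean of
the supplied yields and ``threshold=79`` reproduces the published rule
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .data_model import ReactionRecord
from .errors import ConfigError


def stratified_split(records: Sequence[ReactionRecord]) -> list[ReactionRecord]:
    """Assign ``split_label`` deterministically (returns record copies).

    Stable sort key: (reaction type, yield descending, original index);
    every fourth record of the sorted order is validation ("v"), the rest
    training ("t").
    """
    n = len(records)
    order = sorted(
        range(n),
        key=lambda i: (
            records[i].reaction_type,
            -(records[i].yield_pct if records[i].yield_pct is not None else -np.inf),
            i,
        ),
    )
    labels = ["t"] * n
    for pos, i in enumerate(order, start=1):
        if pos % 4 == 0:
            labels[i] = "v"
    out = []
    for r, lab in zip(records, labels):
        c = r.copy()
        c.split_label = lab
        out.append(c)
    return out


def split_labels(reaction_types: Sequence[str], yields: Sequence[float]) -> np.ndarray:
    """Array form of :func:`stratified_split` for tabular pipelines."""
    n = len(reaction_types)
    order = sorted(range(n), key=lambda i: (reaction_types[i], -yields[i], i))
    labels = np.array(["t"] * n, dtype=object)
    for pos, i in enumerate(order, start=1):
        if pos % 4 == 0:
            labels[i] = "v"
    return labels


def binarize_yield(
    yields: Sequence[float] | pd.Series, threshold: float | None = None
) -> np.ndarray:
    """1 iff yield > threshold, 0 iff yield ≤ threshold.

    ``threshold=None`` uses the mean of ``yields``; pass 79 for the
    published rule.
    """
    y = np.asarray(yields, dtype=float)
    if threshold is None:
        threshold = float(np.mean(y))
    return (y > threshold).astype(int)


@dataclass
class MetricsReport:
    subset: str
    n: int
    R: float | None = None
    mae: float | None = None
    rmse: float | None = None
    stratified: dict[str, dict[str, float]] = dc_field(default_factory=dict)
    # classification block
    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    tpr_pct: float | None = None
    tnr_pct: float | None = None
    auc: float | None = None
    confusion: dict[str, int] = dc_field(default_factory=dict)
    roc_points: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("roc_points",) and v is not None and v != {}
        }
        return out


def _mae_rmse(err: np.ndarray) -> tuple[float, float]:
    return float(np.mean(np.abs(err))), float(np.sqrt(np.mean(err**2)))


def regression_metrics(
    observed: Sequence[float],
    predicted: Sequence[float],
    threshold: float = 79.0,
    subset: str = "train",
) -> MetricsReport:
    """Pearson R, MAE and RMSE, additionally stratified by the observed
    yield band (≤ threshold vs > threshold)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ConfigError("observed/predicted must be equal-length with n >= 2")
    err = obs - pred
    mae, rmse = _mae_rmse(err)
    if np.std(obs) == 0 or np.std(pred) == 0:
        warnings.warn("zero variance: Pearson R undefined", stacklevel=2)
        R = None
    else:
        R = float(np.corrcoef(obs, pred)[0, 1])
    stratified = {}
    for name, mask in (("low", obs <= threshold), ("high", obs > threshold)):
        if mask.any():
            m, r = _mae_rmse(err[mask])
            stratified[name] = {"mae": m, "rmse": r, "n": int(mask.sum())}
    return MetricsReport(subset=subset, n=obs.size, R=R, mae=mae, rmse=rmse, stratified=stratified)


def rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the rank (Mann–Whitney) statistic with tied scores averaged."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ConfigError("AUC undefined for single-class labels")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def classification_metrics(
    labels: Sequence[int],
    probabilities: Sequence[float],
    cutoff: float = 0.5,
    subset: str = "train",
) -> MetricsReport:
    """Confusion matrix at ``cutoff``, precision/recall/F1/accuracy,
    TPR/TNR percentages, rank-statistic AUC, and ROC curve points."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ConfigError("probabilities must lie in [0, 1]")
    pred = (p >= cutoff).astype(int)
    tp = int(np.sum((y == 1) & (pred == 1)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    n = y.size
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision not in (None, 0) and recall not in (None, 0)
        else None
    )
    tpr = 100.0 * tp / (tp + fn) if (tp + fn) else None
    tnr = 100.0 * tn / (tn + fp) if (tn + fp) else None
    if len(np.unique(y)) < 2:
        warnings.warn("single-class labels: AUC undefined", stacklevel=2)
        auc = None
        roc = None
    else:
        auc = rank_auc(y, p)
        fpr, tpr_curve, thr = roc_curve(y, p)
        roc = pd.DataFrame({"fpr": fpr, "tpr": tpr_curve, "threshold": thr})
    return MetricsReport(
        subset=subset,
        n=n,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        tpr_pct=tpr,
        tnr_pct=tnr,
        auc=auc,
        confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
        roc_points=roc,
    )


def feature_importance(
    model,
    features: pd.DataFrame,
    targets: Sequence,
    n_repeats: int = 10,
    seed: int = 0,
    task: str | None = None,
) -> pd.DataFrame:
    """Permutation importance: mean drop of the quality metric (accuracy
    for classifiers, Pearson R for regressors) when a column is shuffled.

    ``model`` needs ``predict`` (and ``predict_proba`` for classifiers).
    Returns a frame sorted by descending importance.
    """
    if features.shape[1] < 2:
        raise ConfigError("need at least 2 features")
    rng = np.random.default_rng(seed)
    y = np.asarray(targets)
    if task is None:
        task = "classification" if hasattr(model, "predict_proba") else "regression"

    def score(frame: pd.DataFrame) -> float:
        if task == "classification":
            proba = model.predict_proba(frame)
            p1 = proba[:, 1] if proba.ndim == 2 else proba
            return float(np.mean((p1 >= 0.5).astype(int) == y))
        pred = np.asarray(model.predict(frame), dtype=float)
        if np.std(pred) == 0 or np.std(y) == 0:
            return 0.0
        return float(np.corrcoef(y.astype(float), pred)[0, 1])

    base = score(features)
    rows = []
    for col in features.columns:
        drops = []
        for _ in range(n_repeats):
            shuffled = features.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            drops.append(base - score(shuffled))
        rows.append({"feature": col, "importance": float(np.mean(drops)), "std": float(np.std(drops))})
    frame = pd.DataFrame(rows).sort_values("importance", ascending=False, kind="stable")
    return frame.reset_index(drop=True)


def dataset_summary(
    records: Sequence[ReactionRecord],
    excluded_type: str = "double_carbonylation",
) -> dict[str, float]:
    """Headline bookkeeping of a dataset under the every-4th split rule:
    training-set sizes with and without the excluded reaction family, and
    the full-dataset mean yield (the binarization threshold source)."""
    n = len(records)
    n_sub = sum(1 for r in records if r.reaction_type != excluded_type)
    yields = [r.yield_pct for r in records if r.yield_pct is not None]
    return {
        "n_total": n,
        "train_size_all": n - n // 4,
        "train_size_excluding": n_sub - n_sub // 4,
        "mean_yield": float(np.mean(yields)) if yields else float("nan"),
    }
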