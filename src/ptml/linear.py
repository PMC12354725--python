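"""PTML multiple linear regression.

The model is

    Yld(%)_n = a0 + a1 * f_ref + sum_k b_k * Delta_k

where ``f_ref`` is the reference yield (the record's reuse-cycle cohort
mean) and ``Delta_k`` are the perturbation features of a recipe.  The
reference column is privileged: it is always retained and never subject to
stepwise removal.

Besides ordinary fitting this module provides the forward-stepwise (FSW)
and expert-guided (EGS) selection procedures, leave-one-out and
leave-group-out cross-validation, and the two published equations as
built-in, bit-exact evaluators.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import ConfigError, ContractError, SingularityError

_RANK_TOL = 1e-8


@dataclass
class PTMLLinearModel:
    a0: float
    a1: float
    b: dict[str, float]  # ordered coefficients, keyed by term id
    recipe_ref: str = ""
    scheme_ref: str = ""

    @property
    def term_ids(self) -> tuple[str, ...]:
        return tuple(self.b)

    def to_json(self) -> str:
        return json.dumps(
            {
                "a0": self.a0,
                "a1": self.a1,
                "b": self.b,
                "recipe_ref": self.recipe_ref,
                "scheme_ref": self.scheme_ref,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PTMLLinearModel":
        raw = json.loads(text)
        return cls(raw["a0"], raw["a1"], dict(raw["b"]), raw.get("recipe_ref", ""), raw.get("scheme_ref", ""))


@dataclass
class FitDiagnostics:
    n: int
    R: float
    mae: float
    rmse: float
    p_values: dict[str, float]
    residuals: pd.Series


def _design(features: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = ["reference", *terms]
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ContractError(f"feature table lacks columns {missing}")
    X = features[cols].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(X)), X])


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(X, tol=_RANK_TOL * max(1.0, np.abs(X).max())) < X.shape[1]:
        # locate dependent columns with a pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        thresh = diag.max() * 1e-10 if diag.size else 0.0
        bad = [piv[i] for i in range(len(diag)) if diag[i] <= thresh]
        all_names = ["intercept", "reference", *names[2:]] if len(names) == X.shape[1] else list(names)
        raise SingularityError([str(all_names[i]) for i in bad])


def fit_mlr(
    features: pd.DataFrame,
    yields: Mapping[str, float] | pd.Series,
    terms: Sequence[str] | None = None,
) -> tuple[PTMLLinearModel, FitDiagnostics]:
    """Ordinary least squares fit of the PTML linear model.

    ``terms`` restricts the perturbation columns used (default: all
    non-reference columns, in table order).  Requires at least
    ``len(terms) + 2`` rows and a full-rank design.
    """
    if terms is None:
        terms = [c for c in features.columns if c != "reference"]
    terms = list(terms)
    y = pd.Series(yields).reindex(features.index)
    if y.isna().any():
        raise ContractError("yields missing for some feature rows")
    n, p = len(features), len(terms) + 2
    if n < p:
        raise ConfigError(f"need at least {p} rows for {len(terms)} terms, got {n}")
    names = ["intercept", "reference", *terms]
    X = _design(features, terms)
    _check_rank(X, names)
    res = sm.OLS(y.to_numpy(dtype=float), X).fit()
    coef = res.params
    model = PTMLLinearModel(
        a0=float(coef[0]),
        a1=float(coef[1]),
        b={t: float(c) for t, c in zip(terms, coef[2:])},
        recipe_ref=features.attrs.get("recipe_id", ""),
        scheme_ref=features.attrs.get("scheme_id", ""),
    )
    fitted = res.fittedvalues
    resid = y.to_numpy(dtype=float) - fitted
    if np.std(fitted) > 0 and np.std(y) > 0:
        R = float(np.corrcoef(y, fitted)[0, 1])
    else:
        R = float("nan")
    diag = FitDiagnostics(
        n=n,
        R=R,
        mae=float(np.mean(np.abs(resid))),
        rmse=float(np.sqrt(np.mean(resid**2))),
        p_values={nm: float(p_) for nm, p_ in zip(names, res.pvalues)},
        residuals=pd.Series(resid, index=features.index),
    )
    return model, diag


def predict(model: PTMLLinearModel, features: pd.DataFrame) -> pd.Series:
    """Evaluate ``a0 + a1·reference + Σ b_k·Δ_k`` per row.

    Predictions are deliberately not clipped to [0, 100]; use ``clip=True``
    downstream for reporting if desired.
    """
    if "reference" not in features.columns:
        raise ContractError("feature table lacks the reference column")
    missing = [t for t in model.b if t not in features.columns]
    if missing:
        raise ContractError(f"feature table lacks model terms {missing}")
    out = model.a0 + model.a1 * features["reference"].astype(float)
    for t, c in model.b.items():
        out = out + c * features[t].astype(float)
    return out.rename("predicted")


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def forward_stepwise(
    features: pd.DataFrame,
    yields: Mapping[str, float] | pd.Series,
    max_steps: int = 10,
    enter_p: float = 0.05,
) -> list[str]:
    """Greedy forward selection by partial F-to-enter.

    The intercept and reference columns form the base model.  At each step
    the candidate with the largest F statistic joins if its p-value is
    below ``enter_p``; ties are broken by column (recipe) order.  Stops at
    ``max_steps`` or when no candidate qualifies.
    """
    if max_steps < 1:
        raise ConfigError("max_steps must be >= 1")
    y = pd.Series(yields).reindex(features.index).to_numpy(dtype=float)
    candidates = [c for c in features.columns if c != "reference"]
    selected: list[str] = []
    n = len(features)
    while len(selected) < max_steps and len(selected) < len(candidates):
        X0 = _design(features, selected)
        rss0 = _rss(X0, y)
        best: tuple[float, int, str] | None = None
        for order, cand in enumerate(candidates):
            if cand in selected:
                continue
            X1 = np.column_stack([X0, features[cand].to_numpy(dtype=float)])
            df_resid = n - X1.shape[1]
            if df_resid <= 0:
                continue
            rss1 = _rss(X1, y)
            if rss1 <= 1e-12 * max(rss0, 1.0):
                F = np.inf
            else:
                F = (rss0 - rss1) / (rss1 / df_resid)
            # strictly-greater comparison keeps the earliest column on ties
            if best is None or F > best[0] + 1e-12:
                best = (F, order, cand)
        if best is None:
            break
        F, _, cand = best
        df_resid = n - (len(selected) + 3)
        p_val = 0.0 if np.isinf(F) else float(scipy.stats.f.sf(F, 1, max(df_resid, 1)))
        if not (p_val < enter_p):
            break
        selected.append(cand)
    return selected


def expert_guided_selection(
    base_selection: Sequence[str],
    forced_terms: Sequence[str],
    known_terms: Sequence[str] | None = None,
) -> list[str]:
    """Union of an automatic selection and expert-forced terms.

    Order: FSW order first, then forced order; duplicates dropped.
    """
    if known_terms is not None:
        unknown = [t for t in forced_terms if t not in known_terms]
        if unknown:
            raise ConfigError(f"unknown forced terms {unknown}")
    out = list(base_selection)
    for t in forced_terms:
        if t not in out:
            out.append(t)
    return out


# ---------------------------------------------------------------------------
# Published models
# ---------------------------------------------------------------------------

_PUBLISHED_TERM_IDS = (
    "d(D2*V2)",
    "dV31",
    "dV33",
    "d(V11*V13)",
    "d(V29*(V22+V26))",
    "d(D6*V8)",
    "d(D15*(V10+V35))",
    "dV30",
)

_PUBLISHED = {
    # full-dataset PTML 3 equation (851 training points)
    "eq5": (
        2.0103,
        0.9749,
        (0.0001, 0.0144, 0.9899, 0.1526, -2.9991, 14.2967, -14.1591, 1.0950),
    ),
    # PTML 3 equation without the double-carbonylation subset (789 points)
    "eq6": (
        1.7555,
        0.9731,
        (0.00003, 0.0381, 1.0443, -0.2962, -2.7938, 16.8403, -16.5780, 1.0987),
    ),
}


def published_model(model_id: str) -> PTMLLinearModel:
    """The printed coefficients of a published PTML 3 equation, stored at
    typeset precision and never re-derived."""
    if model_id not in _PUBLISHED:
        raise ConfigError(f"unknown published model {model_id!r}")
    a0, a1, b = _PUBLISHED[model_id]
    return PTMLLinearModel(
        a0=a0,
        a1=a1,
        b=dict(zip(_PUBLISHED_TERM_IDS, b)),
        recipe_ref=model_id,
        scheme_ref="PTML3",
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class LooReport:
    predictions: pd.Series
    residuals: pd.Series
    relative_errors: pd.Series
    skipped: list[str] = dc_field(default_factory=list)
    #: mean relative LOO error per group, when groups were given
    group_errors: dict[str, float] = dc_field(default_factory=dict)


def loo_cv(
    features: pd.DataFrame,
    yields: Mapping[str, float] | pd.Series,
    selection: Sequence[str] | None = None,
    groups: Mapping[str, str] | pd.Series | None = None,
    rel_eps: float = 1.0,
) -> LooReport:
    """Leave-one-out cross-validation of the linear model.

    Relative error per row is ``|obs − pred| / max(obs, rel_eps)``; the
    floor avoids blow-up at near-zero yields.  When ``groups`` (e.g.
    reaction types) are given, mean relative errors per group are reported
    so systematically mispredicted subsets stand out.
    """
    terms = list(selection) if selection is not None else [
        c for c in features.columns if c != "reference"
    ]
    y = pd.Series(yields).reindex(features.index).to_numpy(dtype=float)
    n = len(features)
    if n < 3:
        raise ConfigError("need at least 3 rows for leave-one-out")
    X = _design(features, terms)
    preds = np.full(n, np.nan)
    skipped: list[str] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi, yi = X[mask], y[mask]
        if np.linalg.matrix_rank(Xi) < Xi.shape[1]:
            warnings.warn(f"LOO fold {features.index[i]}: singular fit, skipped", stacklevel=2)
            skipped.append(str(features.index[i]))
            continue
        beta, _, _, _ = np.linalg.lstsq(Xi, yi, rcond=None)
        preds[i] = X[i] @ beta
    pred = pd.Series(preds, index=features.index, name="loo_prediction")
    resid = pd.Series(y, index=features.index) - pred
    rel = (resid.abs() / np.maximum(y, rel_eps)).rename("relative_error")
    report = LooReport(pred, resid.rename("residual"), rel, skipped)
    if groups is not None:
        g = pd.Series(groups).reindex(features.index)
        report.group_errors = rel.groupby(g).mean().to_dict()
    return report


@dataclass
class LgoReport:
    model: PTMLLinearModel
    diagnostics: FitDiagnostics
    excluded: int


def leave_group_out_cv(
    features: pd.DataFrame,
    yields: Mapping[str, float] | pd.Series,
    groups: Mapping[str, str] | pd.Series,
    held_group: str,
    terms: Sequence[str] | None = None,
) -> LgoReport:
    """Refit with every record of ``held_group`` removed from both training
    and evaluation, reporting metrics on the reduced population."""
    g = pd.Series(groups).reindex(features.index)
    keep = g != held_group
    if not keep.any():
        raise ConfigError(f"group {held_group!r} absorbs all data")
    sub = features.loc[keep]
    y = pd.Series(yields).reindex(features.index).loc[keep]
    model, diag = fit_mlr(sub, y, terms=terms)
    return LgoReport(model, diag, excluded=int((~keep).sum()))
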