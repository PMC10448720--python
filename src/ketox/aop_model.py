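"""Logistic in vivo hepatotoxicity models with leave-one-out validation.

Model 1 uses only scaled KE scores as predictors.  Model 2 adds
bioavailability information: log10 Css plus Lipinski-type descriptors.
Classes are balanced once by random undersampling of the majority class
before validation; leave-one-out cross-validation then refits the model n
times, each time predicting the held-out chemical, and classifies at a
fixed probability threshold of 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

DEFAULT_THRESHOLD = 0.5
DEFAULT_C = 1.0  # inverse L2 penalty strength; weak relative to typical n


@dataclass
class AopModelResult:
    """Per-chemical probabilities plus confusion metrics for one model."""

    model_id: int
    probabilities: pd.Series  # chem_id -> P(hepatotoxic)
    actual: pd.Series
    threshold: float = DEFAULT_THRESHOLD
    coefficients: Optional[pd.DataFrame] = None
    predicted: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.predicted = (self.probabilities > self.threshold).astype(int)

    @property
    def confusion(self) -> dict[str, int]:
        y, p = self.actual.astype(int), self.predicted
        return {
            "TP": int(((y == 1) & (p == 1)).sum()),
            "FP": int(((y == 0) & (p == 1)).sum()),
            "TN": int(((y == 0) & (p == 0)).sum()),
            "FN": int(((y == 1) & (p == 0)).sum()),
        }

    @property
    def accuracy(self) -> float:
        c = self.confusion
        return (c["TP"] + c["TN"]) / len(self.actual)

    @property
    def recall(self) -> float:
        c = self.confusion
        denom = c["TP"] + c["FN"]
        return c["TP"] / denom if denom else float("nan")

    def metrics(self) -> dict:
        c = self.confusion
        return {
            "model_id": self.model_id,
            "n": len(self.actual),
            **c,
            "accuracy": self.accuracy,
            "recall": self.recall,
        }


def undersample_balance(labels: pd.Series, seed: int) -> list[str]:
    """Balanced chem_id subset: all of the minority class, an equal-size
    uniform random draw from the majority class.  Deterministic given seed."""
    y = labels.dropna().astype(int)
    pos = y.index[y == 1]
    neg = y.index[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("undersample_balance: both classes must be present")
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    rng = np.random.default_rng(seed)
    kept_majority = rng.choice(np.asarray(majority, dtype=object), size=len(minority), replace=False)
    return sorted(list(minority) + list(kept_majority))


def build_features(
    ke_scores: pd.DataFrame,
    labels: pd.DataFrame,
    model_id: int,
    css: Optional[pd.Series] = None,
    descriptors: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the feature table and label vector for Model 1 or 2.

    Model 1: scaled KE scores only.  Model 2 additionally requires Css
    (entered as log10 uM) and Lipinski descriptors; chemicals missing either
    are dropped.  Rows are restricted to labeled chemicals and the result
    contains no missing values.
    """
    if model_id not in (1, 2):
        raise ValueError("model_id must be 1 or 2")
    X = ke_scores.copy()
    keep = X.index.intersection(labels.index[labels["hepatotoxic"].notna()])
    if model_id == 2:
        if css is None or descriptors is None:
            raise ValueError("Model 2 requires css and descriptors")
        keep = keep.intersection(css.dropna().index).intersection(descriptors.dropna().index)
        X = X.loc[keep]
        X["log10_css"] = np.log10(css.loc[keep].astype(float))
        X = X.join(descriptors.loc[keep])
    else:
        X = X.loc[keep]
    y = labels.loc[keep, "hepatotoxic"].astype(int)
    X = X.sort_index()
    return X, y.sort_index()


def _make_estimator(C: float = DEFAULT_C, penalize: bool = True) -> Pipeline:
    # C=inf turns the L2 penalty off without touching deprecated kwargs
    logit = LogisticRegression(C=C if penalize else np.inf, solver="lbfgs", max_iter=5000, tol=1e-10)
    return Pipeline([("scale", StandardScaler()), ("logit", logit)])


def fit_logistic(
    X: pd.DataFrame, y: pd.Series, C: float = DEFAULT_C, penalize: bool = True
) -> tuple[Pipeline, pd.DataFrame]:
    """Fit the standardized, weakly L2-penalized logistic model.

    Returns the fitted pipeline and a coefficient table (on the
    standardized scale) with the intercept as feature ``(intercept)``.
    """
    model = _make_estimator(C=C, penalize=penalize)
    model.fit(X.to_numpy(), y.to_numpy())
    logit: LogisticRegression = model.named_steps["logit"]
    coef = pd.DataFrame(
        {
            "feature": ["(intercept)"] + list(X.columns),
            "coefficient": [float(logit.intercept_[0])] + [float(c) for c in logit.coef_[0]],
        }
    )
    return model, coef


def loo_cv(
    X: pd.DataFrame,
    y: pd.Series,
    model_id: int = 1,
    C: float = DEFAULT_C,
    penalize: bool = True,
    threshold: float = DEFAULT_THRESHOLD,
) -> AopModelResult:
    """Leave-one-out validation: n refits, each predicting the held-out chemical.

    The held-out chemical's label is never visible to the fold that predicts
    it.  Coefficients reported come from a final fit on the full data.
    """
    if len(X) < 4:
        raise ValueError("loo_cv needs n >= 4")
    if y.nunique() < 2:
        raise ValueError("loo_cv needs both classes present")
    if not X.index.equals(y.index):
        raise ValueError("features and labels must share an index")
    Xa, ya = X.to_numpy(dtype=float), y.to_numpy(dtype=int)
    probs = np.empty(len(X))
    for i in range(len(X)):
        mask = np.ones(len(X), dtype=bool)
        mask[i] = False
        if len(np.unique(ya[mask])) < 2:
            # degenerate fold: constant-class training data, predict the base rate
            probs[i] = float(ya[mask].mean())
            continue
        model = _make_estimator(C=C, penalize=penalize)
        model.fit(Xa[mask], ya[mask])
        probs[i] = float(model.predict_proba(Xa[i : i + 1])[0, 1])
    _, coef = fit_logistic(X, y, C=C, penalize=penalize)
    ttest = feature_group_test(X, y).set_index("feature")
    coef = coef.join(ttest, on="feature")
    return AopModelResult(
        model_id=model_id,
        probabilities=pd.Series(probs, index=X.index),
        actual=y,
        threshold=threshold,
        coefficients=coef,
    )


def feature_group_test(X: pd.DataFrame, y: pd.Series) -> pd.DataFrame:
    """Welch two-sample t test per feature between toxic and nontoxic groups.

    Returns ``feature,t_stat,p_value`` ranked by |t| descending.  Features
    constant and identical in both groups get t=0, p=1; constant but
    different groups get an infinite statistic and p=0.
    """
    yi = y.astype(int)
    g1 = X.loc[yi == 1]
    g0 = X.loc[yi == 0]
    rows = []
    for col in X.columns:
        a, b = g1[col].to_numpy(dtype=float), g0[col].to_numpy(dtype=float)
        if np.var(a) == 0 and np.var(b) == 0:
            if a.size and b.size and a[0] == b[0]:
                t, p = 0.0, 1.0
            else:
                t, p = math.inf if (a.size and b.size and a[0] > b[0]) else -math.inf, 0.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"feature": col, "t_stat": float(t), "p_value": float(p)})
    out = pd.DataFrame(rows, columns=["feature", "t_stat", "p_value"])
    return out.reindex(out["t_stat"].abs().sort_values(ascending=False).index).reset_index(drop=True)


def compare_models(result1: AopModelResult, result2: AopModelResult) -> dict:
    """Accuracy/recall deltas and the chemicals Model 2 corrects over Model 1."""
    common = result1.actual.index.intersection(result2.actual.index)
    wrong1 = result1.predicted.loc[common] != result1.actual.loc[common]
    right2 = result2.predicted.loc[common] == result2.actual.loc[common]
    corrected = sorted(common[wrong1 & right2])
    return {
        "accuracy_delta": result2.accuracy - result1.accuracy,
        "recall_delta": result2.recall - result1.recall,
        "corrected": corrected,
        "n_corrected": len(corrected),
    }


def prediction_table(result: AopModelResult) -> pd.DataFrame:
    """Per-chemical export: ``chem_id,model_id,probability,predicted,actual``."""
    return pd.DataFrame(
        {
            "chem_id": result.probabilities.index,
            "model_id": result.model_id,
            "probability": result.probabilities.to_numpy(),
            "predicted": result.predicted.to_numpy(),
            "actual": result.actual.astype(int).to_numpy(),
        }
    )
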