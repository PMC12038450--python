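"""Sensitive-index selection: Pearson screening and RFECV.

Two filters pick the vegetation indices most responsive to needle water
content: a univariate Pearson screen (keep |r| above a threshold,
default 0.4) followed by recursive feature elimination with
cross-validation (RFECV).  The RFE ranking estimator is a linear
support-vector regressor on standardized features — RBF-kernel SVR
exposes no native importances, so the standard linear-weight RFE
construction is used — while the final predictive models are fit
separately (see :mod:`larchwc.regression`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVR

from larchwc.metrics import rmse

__all__ = [
    "SelectionResult",
    "pearson_r",
    "correlation_screen",
    "rfecv",
    "REFERENCE_SENSITIVE_INDICES",
]

#: Sensitive-index sets selected on the original field campaign, shipped as
#: reference configuration (3 indices for LWCF, 10 for LWCD).
REFERENCE_SENSITIVE_INDICES: dict[str, tuple[str, ...]] = {
    "LWCF": ("SIreg", "AFRI1600", "SCCI"),
    "LWCD": ("NLI2", "SIreg", "AFRI1600", "CCRI", "CTVI",
             "Int2", "NDMI", "NLI", "SCCI", "SI1"),
}


def pearson_r(feature, target):
    """Sample Pearson correlation; returns ``(r, reason)``.

    ``r`` is NaN with a reason when either input has zero variance or
    fewer than 3 paired finite observations.
    """
    x = np.asarray(feature, dtype=float).ravel()
    y = np.asarray(target, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("feature and target lengths differ")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        return float("nan"), "fewer than 3 paired observations"
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), "zero variance"
    r = stats.pearsonr(x, y).statistic
    return float(r), None


def correlation_screen(
    table: pd.DataFrame,
    target: str,
    threshold: float = 0.4,
) -> list[str]:
    """Keep features with |r| against the target above ``threshold``.

    If nothing survives, warns and passes all features through (the
    screen is a pre-filter, not a hard gate).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if target not in table.columns:
        raise KeyError(f"target column {target!r} not in table")
    y = table[target]
    features = [c for c in table.columns if c != target]
    kept = []
    for name in features:
        r, reason = pearson_r(table[name], y)
        if reason is None and abs(r) > threshold:
            kept.append(name)
    if not kept:
        warnings.warn(
            f"no feature exceeded |r| > {threshold}; passing all features through",
            RuntimeWarning,
        )
        return features
    return kept


@dataclass
class SelectionResult:
    """Outcome of RFECV.

    ``ranking`` is the elimination order (first eliminated first, the
    survivor last); ``scores`` maps subset size -> mean CV score
    (negative RMSE); ``selected`` is the CV-optimal subset.
    """

    ranking: list[str]
    selected: list[str]
    scores: dict[int, float] = field(default_factory=dict)
    threshold: float | None = None
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "ranking": self.ranking,
            "selected": self.selected,
            "scores": {str(k): v for k, v in self.scores.items()},
            "threshold": self.threshold,
            "seed": self.seed,
        }


def _cv_score(X: np.ndarray, y: np.ndarray, folds: int, seed: int, svr_c: float) -> float:
    """Mean negative RMSE over shuffled k-fold CV."""
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in kf.split(X):
        model = make_pipeline(
            StandardScaler(),
            LinearSVR(C=svr_c, epsilon=0.0, max_iter=10000, random_state=seed),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X[tr], y[tr])
        scores.append(-rmse(y[te], model.predict(X[te])))
    return float(np.mean(scores))


def rfecv(
    table: pd.DataFrame,
    target: str,
    folds: int = 5,
    seed: int = 0,
    svr_c: float = 1.0,
    min_features: int = 1,
) -> SelectionResult:
    """Recursive feature elimination with cross-validated subset scoring.

    At each step a linear SVR is fit on the remaining standardized
    features; the current subset is scored by ``folds``-fold CV (negative
    RMSE) and the feature with the smallest |coefficient| is dropped.
    After full elimination the subset size with the highest mean CV score
    is returned (ties favour the smaller subset).  Deterministic given
    ``seed``.
    """
    if target not in table.columns:
        raise KeyError(f"target column {target!r} not in table")
    y = table[target].to_numpy(dtype=float)
    if np.ptp(y[np.isfinite(y)]) == 0:
        raise ValueError("target has zero variance")
    features = [c for c in table.columns if c != target]
    if len(features) < 1:
        raise ValueError("need at least one feature")
    work = table[features + [target]].dropna()
    X_all = work[features].to_numpy(dtype=float)
    y = work[target].to_numpy(dtype=float)
    if y.size < folds:
        raise ValueError(f"n={y.size} rows is fewer than {folds} CV folds")

    current = list(features)
    eliminated: list[str] = []
    scores: dict[int, float] = {}
    while True:
        idx = [features.index(f) for f in current]
        X = X_all[:, idx]
        scores[len(current)] = _cv_score(X, y, folds, seed, svr_c)
        if len(current) <= min_features:
            break
        scaler = StandardScaler().fit(X)
        svr = LinearSVR(C=svr_c, epsilon=0.0, max_iter=10000, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            svr.fit(scaler.transform(X), y)
        weakest = int(np.argmin(np.abs(svr.coef_)))
        eliminated.append(current.pop(weakest))

    ranking = eliminated + current  # first eliminated ... survivor
    best_size = max(sorted(scores), key=lambda k: (scores[k], -k))
    selected = ranking[len(ranking) - best_size:]
    selected = [f for f in features if f in set(selected)]  # stable order
    return SelectionResult(
        ranking=ranking, selected=selected, scores=scores, seed=seed,
    )
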