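"""Water-content estimators: RBF-kernel SVR and a BP neural network.

Both models follow the stated training protocol: support vector
regression with an RBF kernel, C = 10 and gamma = 0.1; and a
back-propagation network with one 40-node hidden layer, learning rate
0.01, plain gradient descent, at most 1000 epochs and early stopping on
the training loss.  Features are z-scored on the training rows only;
the BP target is min-max scaled for gradient-descent stability and
inverse-transformed on output.  Model skill is evaluated by
leave-one-out cross-validation with MAE and RMSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from larchwc.metrics import mae, rmse

__all__ = [
    "SVRConfig",
    "BPConfig",
    "EvalMetrics",
    "fit_predict_svr",
    "fit_predict_bp",
    "loocv",
    "mae",
    "rmse",
]


@dataclass(frozen=True)
class SVRConfig:
    """RBF-kernel support vector regression hyperparameters."""

    C: float = 10.0
    gamma: float = 0.1
    epsilon: float = 0.1
    standardize: bool = True

    def __post_init__(self):
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


@dataclass(frozen=True)
class BPConfig:
    """Back-propagation network hyperparameters."""

    hidden: int = 40
    learning_rate: float = 0.01
    max_iter: int = 1000
    patience: int = 50           # epochs without training-loss improvement
    tol: float = 1e-6
    activation: str = "logistic"  # sigmoid hidden layer, linear output
    seed: int = 0

    def __post_init__(self):
        if self.hidden < 1:
            raise ValueError("hidden must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class EvalMetrics:
    """LOOCV (or holdout) evaluation: MAE, RMSE and aligned predictions."""

    mae: float
    rmse: float
    y: np.ndarray
    y_hat: np.ndarray
    n: int

    def __post_init__(self):
        # Power-mean inequality; violation indicates a metric bug.
        if self.mae > self.rmse + 1e-12:
            raise ValueError("MAE exceeded RMSE; inconsistent metric computation")

    def as_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "n": self.n}


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X[:, None] if X.ndim == 1 else X


def fit_predict_svr(X_train, y_train, X_test, config: SVRConfig | None = None) -> np.ndarray:
    """Train epsilon-insensitive RBF SVR and predict on ``X_test``.

    Standardization statistics come from the training rows only.  A
    constant training target short-circuits to that constant (with a
    warning): the dual problem is degenerate there.
    """
    config = config or SVRConfig()
    X_train, X_test = _as_2d(X_train), _as_2d(X_test)
    y_train = np.asarray(y_train, dtype=float).ravel()
    if np.ptp(y_train) == 0:
        warnings.warn("constant training target; predicting the constant", RuntimeWarning)
        return np.full(X_test.shape[0], y_train[0])
    if config.standardize:
        scaler = StandardScaler().fit(X_train)
        X_train, X_test = scaler.transform(X_train), scaler.transform(X_test)
    model = SVR(kernel="rbf", C=config.C, gamma=config.gamma, epsilon=config.epsilon)
    model.fit(X_train, y_train)
    return model.predict(X_test)


def fit_predict_bp(X_train, y_train, X_test, config: BPConfig | None = None) -> np.ndarray:
    """Train the one-hidden-layer BP network and predict on ``X_test``.

    Plain (momentum-free) SGD at a constant learning rate; training stops
    when the loss has not improved by ``tol`` for ``patience`` epochs or
    at ``max_iter``.  The target is min-max scaled during training and
    predictions are mapped back to the original scale.
    """
    config = config or BPConfig()
    X_train, X_test = _as_2d(X_train), _as_2d(X_test)
    y_train = np.asarray(y_train, dtype=float).ravel()
    lo, hi = float(y_train.min()), float(y_train.max())
    if hi - lo == 0:
        warnings.warn("constant training target; predicting the constant", RuntimeWarning)
        return np.full(X_test.shape[0], lo)
    y_scaled = (y_train - lo) / (hi - lo)
    scaler = StandardScaler().fit(X_train)
    model = MLPRegressor(
        hidden_layer_sizes=(config.hidden,),
        activation=config.activation,
        solver="sgd",
        learning_rate="constant",
        learning_rate_init=config.learning_rate,
        momentum=0.0,
        nesterovs_momentum=False,
        alpha=0.0,
        batch_size=min(32, X_train.shape[0]),
        max_iter=config.max_iter,
        tol=config.tol,
        n_iter_no_change=config.patience,
        early_stopping=False,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(scaler.transform(X_train), y_scaled)
    if not np.isfinite(model.loss_):
        raise FloatingPointError(
            "BP training diverged (loss is not finite); try a smaller learning rate"
        )
    pred = model.predict(scaler.transform(X_test))
    return pred * (hi - lo) + lo


def loocv(table: pd.DataFrame, target: str, fit_predict, config=None) -> EvalMetrics:
    """Leave-one-out cross-validation of a fit/predict function.

    ``fit_predict(X_train, y_train, X_test, config)`` is called n times,
    each predicting a single held-out row; MAE and RMSE are computed over
    the n held-out predictions.
    """
    if target not in table.columns:
        raise KeyError(f"target column {target!r} not in table")
    work = table.dropna()
    features = [c for c in work.columns if c != target]
    X = work[features].to_numpy(dtype=float)
    y = work[target].to_numpy(dtype=float)
    n = y.size
    if n < 3:
        raise ValueError(f"LOOCV needs at least 3 rows, got {n}")
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        try:
            preds[i] = np.asarray(
                fit_predict(X[keep], y[keep], X[~keep], config)
            ).ravel()[0]
        except Exception as exc:
            raise RuntimeError(f"LOOCV fold {i} failed: {exc}") from exc
    return EvalMetrics(mae=mae(y, preds), rmse=rmse(y, preds), y=y, y_hat=preds, n=n)
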