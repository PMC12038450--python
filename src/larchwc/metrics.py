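"""Map-accuracy and regression-error metrics shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionSummary", "confusion_summary", "mae", "rmse"]


@dataclass
class ConfusionSummary:
    """Class-by-class contingency matrix with the standard map accuracies.

    matrix[i, j] counts cells whose reference class is i and predicted
    class is j.  OA is trace/total; UA (user's accuracy, precision) and PA
    (producer's accuracy, recall) are per-class; kappa is the
    chance-corrected agreement from the matrix marginals.  ``kappa`` is
    NaN, with ``kappa_reason`` set, when the expected agreement is 1
    (single-class degenerate case).
    """

    classes: list
    matrix: np.ndarray
    oa: float
    ua: np.ndarray
    pa: np.ndarray
    kappa: float
    n: int
    kappa_reason: str | None = None

    def as_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "matrix": self.matrix.tolist(),
            "oa": self.oa,
            "ua": self.ua.tolist(),
            "pa": self.pa.tolist(),
            "kappa": self.kappa,
            "n": self.n,
        }


def confusion_summary(reference, predicted, classes=None) -> ConfusionSummary:
    """Contingency matrix and OA/UA/PA/kappa for two label vectors."""
    ref = np.asarray(reference).ravel()
    pred = np.asarray(predicted).ravel()
    if ref.shape != pred.shape:
        raise ValueError("reference and predicted label vectors differ in length")
    if ref.size == 0:
        raise ValueError("no overlapping valid cells to compare")
    if classes is None:
        classes = sorted(set(ref.tolist()) | set(pred.tolist()))
    classes = list(classes)
    lut = {c: i for i, c in enumerate(classes)}
    try:
        ri = np.array([lut[v] for v in ref.tolist()])
        pi = np.array([lut[v] for v in pred.tolist()])
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} outside the class list {classes}") from exc
    k = len(classes)
    m = np.zeros((k, k), dtype=np.int64)
    np.add.at(m, (ri, pi), 1)
    n = int(m.sum())
    oa = float(np.trace(m)) / n
    row = m.sum(axis=1)  # reference totals
    col = m.sum(axis=0)  # predicted totals
    with np.errstate(invalid="ignore", divide="ignore"):
        ua = np.where(col > 0, np.diag(m) / col, np.nan)
        pa = np.where(row > 0, np.diag(m) / row, np.nan)
    pe = float((row * col).sum()) / (n * n)
    if abs(1.0 - pe) < 1e-15:
        kappa, reason = float("nan"), "expected agreement is 1 (single observed class)"
    else:
        kappa, reason = (oa - pe) / (1.0 - pe), None
    return ConfusionSummary(
        classes=classes, matrix=m, oa=oa, ua=ua, pa=pa, kappa=kappa, n=n,
        kappa_reason=reason,
    )


def mae(y, y_hat) -> float:
    """Mean absolute error, (1/n) * sum |y_i - y_hat_i|."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.size} observations vs {y_hat.size} predictions")
    return float(np.mean(np.abs(y - y_hat)))


def rmse(y, y_hat) -> float:
    """Root mean square error, sqrt((1/n) * sum (y_i - y_hat_i)^2)."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.size} observations vs {y_hat.size} predictions")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))
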