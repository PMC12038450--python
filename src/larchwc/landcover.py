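"""Supervised Gaussian maximum-likelihood land-cover classification.

The classic ENVI-style MLC: each class is modelled as a multivariate
Gaussian over the ten reflectance bands; a pixel is assigned to the
class maximizing the quadratic discriminant

    g_c(x) = ln pi_c - 1/2 ln|Sigma_c| - 1/2 (x-mu_c)' Sigma_c^-1 (x-mu_c).

The study area splits into forest, water, built-up, agricultural and
bare land; the forest mask feeds the unmixing and mapping stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from larchwc.metrics import ConfusionSummary, confusion_summary
from larchwc.scene import SpectralScene

__all__ = [
    "MLCModel",
    "fit_mlc",
    "classify_mlc",
    "map_accuracy",
    "forest_mask",
    "NODATA_LABEL",
]

#: Label written where a pixel's spectrum is non-finite.
NODATA_LABEL = -1


@dataclass
class MLCModel:
    """Per-class Gaussian parameters for maximum-likelihood classification."""

    classes: list
    means: np.ndarray        # (k, bands)
    covariances: np.ndarray  # (k, bands, bands), ridge-regularized
    priors: np.ndarray       # (k,), sums to 1

    def discriminants(self, X: np.ndarray) -> np.ndarray:
        """g_c(x) for each class; X is (n, bands), returns (n, k)."""
        n = X.shape[0]
        out = np.empty((n, len(self.classes)))
        for i, (mu, cov, pi) in enumerate(zip(self.means, self.covariances, self.priors)):
            L = np.linalg.cholesky(cov)
            diff = X - mu
            sol = np.linalg.solve(L, diff.T)
            maha = np.sum(sol**2, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            out[:, i] = np.log(pi) - 0.5 * logdet - 0.5 * maha
        return out


def fit_mlc(
    samples: np.ndarray,
    labels: np.ndarray,
    equal_priors: bool = False,
    ridge_scale: float = 1e-6,
) -> MLCModel:
    """Fit class means, covariances and priors from labelled spectra.

    Each class needs at least bands+1 samples for a full-rank covariance.
    A ridge of ``ridge_scale`` times the mean band variance is added to
    every covariance so degenerate (e.g. constant-spectrum) classes stay
    invertible.  Priors are proportional to class counts unless
    ``equal_priors`` is set.
    """
    X = np.asarray(samples, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("samples must be (n, bands) with one label per row")
    bands = X.shape[1]
    classes = sorted(set(y.tolist()))
    means, covs, counts = [], [], []
    for c in classes:
        Xc = X[y == c]
        if Xc.shape[0] < bands + 1:
            raise ValueError(
                f"class {c!r} has {Xc.shape[0]} samples; need at least {bands + 1}"
            )
        means.append(Xc.mean(axis=0))
        covs.append(np.cov(Xc, rowvar=False))
        counts.append(Xc.shape[0])
    covs = np.array(covs)
    ridge = ridge_scale * float(np.mean([np.trace(c) / bands for c in covs]))
    ridge = max(ridge, 1e-12)
    covs += ridge * np.eye(bands)
    counts = np.array(counts, dtype=float)
    priors = np.full(len(classes), 1.0 / len(classes)) if equal_priors else counts / counts.sum()
    return MLCModel(classes=classes, means=np.array(means), covariances=covs, priors=priors)


def classify_mlc(model: MLCModel, scene: SpectralScene, bands: list[str] | None = None) -> np.ndarray:
    """Per-pixel argmax of the class discriminants (ties -> first class).

    Requires an all-10 m scene.  Pixels with any non-finite reflectance
    get :data:`NODATA_LABEL`.
    """
    if not scene.is_uniform_10m:
        raise ValueError("classification requires an all-10 m scene; sharpen first")
    names = bands or scene.band_names
    stack = np.stack([scene.bands[b] for b in names])
    h, w = stack.shape[1:]
    X = stack.reshape(len(names), -1).T
    valid = np.all(np.isfinite(X), axis=1) & np.all(X != scene.nodata, axis=1)
    labels = np.full(h * w, NODATA_LABEL, dtype=np.int32)
    if valid.any():
        g = model.discriminants(X[valid])
        labels[valid] = np.argmax(g, axis=1)  # argmax takes the first maximum
    return labels.reshape(h, w)


def map_accuracy(predicted: np.ndarray, reference: np.ndarray) -> ConfusionSummary:
    """Confusion summary over the cells valid in both label rasters."""
    pred = np.asarray(predicted)
    ref = np.asarray(reference)
    if pred.shape != ref.shape:
        raise ValueError(f"rasters are misaligned: {pred.shape} vs {ref.shape}")
    valid = (pred != NODATA_LABEL) & (ref != NODATA_LABEL)
    if not valid.any():
        raise ValueError("zero overlapping valid cells")
    return confusion_summary(ref[valid], pred[valid])


def forest_mask(label_raster: np.ndarray, forest_label: int = 0) -> np.ndarray:
    """Boolean mask of the forest class."""
    return np.asarray(label_raster) == forest_label
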