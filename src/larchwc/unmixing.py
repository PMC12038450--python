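"""Linear spectral unmixing: noise estimation, HySime, VCA and FCLS.

The mixed-pixel chain assumes each pixel spectrum is a convex
combination of a few pure-material spectra (endmembers) plus noise:

    x = E a + n,   a >= 0,  sum(a) = 1.

Four steps, following the original published formulations:

1. :func:`estimate_noise` — per-band multiple regression residuals
   (the noise estimator used by HySime).
2. :func:`hysime` — signal-subspace dimension by minimizing the sum of
   projection error and noise power over eigenvector subsets.
3. :func:`vca` — vertex component analysis: sequential selection of the
   pixels that maximize the projection onto directions orthogonal to
   the span of the endmembers found so far.
4. :func:`fcls` — fully constrained least squares abundances via
   non-negative least squares on a sum-to-one-augmented system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls

__all__ = [
    "EndmemberSet",
    "estimate_noise",
    "hysime",
    "vca",
    "fcls",
    "spectral_angle",
    "align_endmembers",
]


@dataclass
class EndmemberSet:
    """Extracted endmember spectra and the indices of their source pixels."""

    spectra: np.ndarray       # (bands, k)
    pixel_indices: np.ndarray  # (k,) column indices into the pixel matrix

    @property
    def k(self) -> int:
        return self.spectra.shape[1]


def _check_pixel_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("pixel matrix must be 2-D (bands x pixels)")
    if X.shape[0] < 2:
        raise ValueError("pixel matrix needs at least 2 bands")
    if not np.all(np.isfinite(X)):
        raise ValueError("pixel matrix contains non-finite entries")
    return X


def estimate_noise(X: np.ndarray, ridge: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-band regression noise estimate.

    Each band is regressed (least squares) on all the other bands; the
    residuals form that band's noise row.  Returns ``(noise, Rn)`` with
    ``noise`` of shape (bands, pixels) and ``Rn`` the noise correlation
    matrix ``noise @ noise.T / n_pixels``.  Rank-deficient regressions
    fall back to a small ridge with a warning.
    """
    X = _check_pixel_matrix(X)
    bands, n = X.shape
    if n <= bands:
        raise ValueError("need more pixels than bands for noise estimation")
    noise = np.empty_like(X)
    for i in range(bands):
        others = np.delete(np.arange(bands), i)
        Z = X[others].T                              # (n, bands-1)
        zi = X[i]
        G = Z.T @ Z
        if ridge > 0:
            G = G + ridge * np.eye(bands - 1)
        try:
            beta = np.linalg.solve(G, Z.T @ zi)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"band {i}: rank-deficient inter-band regression; using ridge fallback",
                RuntimeWarning,
            )
            beta = np.linalg.solve(G + 1e-8 * np.trace(G) / (bands - 1) * np.eye(bands - 1),
                                   Z.T @ zi)
        noise[i] = zi - Z @ beta
    Rn = noise @ noise.T / n
    return noise, Rn


def hysime(X: np.ndarray, noise: np.ndarray) -> tuple[int, np.ndarray]:
    """Signal-subspace dimension by the minimum-mean-squared-error rule.

    Eigendecomposes the estimated signal correlation matrix and keeps the
    eigenvectors for which including the direction lowers the projection
    MSE, i.e. those with projected signal power exceeding twice the
    projected noise power.  Returns ``(k, basis)`` with ``basis`` of shape
    (bands, k); ``k`` may be 0 for pure noise (degenerate floor).
    """
    X = _check_pixel_matrix(X)
    noise = np.asarray(noise, dtype=float)
    if noise.shape != X.shape:
        raise ValueError("noise matrix shape must match the pixel matrix")
    n = X.shape[1]
    Rn = noise @ noise.T / n
    Ry = X @ X.T / n
    S = X - noise
    Rs = S @ S.T / n
    evals, evecs = np.linalg.eigh(Rs)
    if np.any(evals < -1e-10 * max(1.0, evals.max(initial=0.0))):
        warnings.warn(
            "signal correlation is not PSD after noise subtraction; "
            "clipping negative eigenvalues to 0",
            RuntimeWarning,
        )
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    p_signal = np.einsum("bi,bc,ci->i", evecs, Ry, evecs)
    p_noise = np.einsum("bi,bc,ci->i", evecs, Rn, evecs)
    delta = -p_signal + 2.0 * p_noise  # include direction while this is negative
    keep = delta < 0
    k = int(np.count_nonzero(keep))
    return k, evecs[:, keep]


def spectral_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle (radians) between two spectra; 0 for identical shapes."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        raise ValueError("spectral angle undefined for a zero spectrum")
    return float(np.arccos(np.clip(a @ b / denom, -1.0, 1.0)))


def vca(X: np.ndarray, k: int, seed: int = 0, snr_db: float | None = None) -> EndmemberSet:
    """Vertex component analysis endmember extraction.

    Projects the data to a ``k``-dimensional subspace (projective
    projection at high SNR, mean-removed PCA otherwise; threshold
    ``SNR_th = 15 + 10 log10 k`` dB) and then repeatedly picks the pixel
    with the largest |projection| onto a direction orthogonal to the span
    of the endmembers found so far.  Deterministic given ``seed``.
    """
    X = _check_pixel_matrix(X)
    bands, n = X.shape
    if k <= 0:
        raise ValueError("number of endmembers k must be positive")
    if k > bands:
        raise ValueError(f"k={k} exceeds the number of bands {bands}")
    if n < k:
        raise ValueError(f"need at least k={k} pixels, got {n}")
    rng = np.random.default_rng(seed)

    mean = X.mean(axis=1, keepdims=True)
    Xz = X - mean
    if snr_db is None:
        # SNR estimate from the energy captured by the k-dim PCA subspace.
        Ud = np.linalg.svd(Xz @ Xz.T / n, hermitian=True)[0][:, :k]
        p_y = float(np.sum(X**2)) / n
        p_x = float(np.sum((Ud.T @ X) ** 2)) / n
        denom = p_y - p_x
        num = p_x - (k / bands) * p_y
        if denom <= 1e-15:
            snr_db = 100.0
        elif num <= 0:
            snr_db = -100.0
        else:
            snr_db = 10.0 * np.log10(num / denom)
    snr_th = 15.0 + 10.0 * np.log10(k)

    if snr_db > snr_th:
        d = k
        Ud = np.linalg.svd(X @ X.T / n, hermitian=True)[0][:, :d]
        Xd = Ud.T @ X
        u = Xd.mean(axis=1)
        denom = Xd.T @ u
        denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
        Y = Xd / denom  # projective projection onto the hyperplane y'u = 1
    else:
        d = max(k - 1, 1)
        Ud = np.linalg.svd(Xz @ Xz.T / n, hermitian=True)[0][:, :d]
        Xd = Ud.T @ Xz
        c = float(np.max(np.linalg.norm(Xd, axis=0))) or 1.0
        Y = np.vstack([Xd, np.full(n, c)])

    dim = Y.shape[0]
    indices = np.zeros(k, dtype=int)
    A = np.zeros((dim, k))
    A[-1, 0] = 1.0
    for i in range(k):
        w = rng.standard_normal(dim)
        f = w - A @ np.linalg.pinv(A) @ w
        norm = np.linalg.norm(f)
        if norm < 1e-12:  # span already full; any direction works
            f = rng.standard_normal(dim)
            norm = np.linalg.norm(f)
        f /= norm
        v = f @ Y
        indices[i] = int(np.argmax(np.abs(v)))
        A[:, i] = Y[:, indices[i]]
    return EndmemberSet(spectra=X[:, indices].copy(), pixel_indices=indices)


def fcls(X: np.ndarray, E: np.ndarray, delta: float | None = None) -> np.ndarray:
    """Fully constrained least-squares abundances.

    Per pixel, minimizes ``||x - E a||`` subject to ``a >= 0`` and
    ``sum(a) = 1``, solved by non-negative least squares on the
    sum-to-one-augmented system with augmentation weight
    ``delta = 1 / (20 * max|E|)`` (data rows scaled by delta, a unit
    ones-row appended).  The NNLS solution is finally renormalized onto
    the simplex, so columns sum to 1 to machine precision.

    Returns the (k, pixels) abundance matrix.
    """
    X = _check_pixel_matrix(X)
    E = np.asarray(E, dtype=float)
    if E.ndim != 2 or E.shape[0] != X.shape[0]:
        raise ValueError("endmember matrix must be (bands x k) matching the pixel matrix")
    k = E.shape[1]
    if np.linalg.matrix_rank(E) < k:
        raise ValueError("endmember matrix is rank-deficient")
    if delta is None:
        delta = 1.0 / (20.0 * float(np.max(np.abs(E))))
    A = np.vstack([delta * E, np.ones((1, k))])
    n = X.shape[1]
    out = np.empty((k, n))
    b = np.empty(A.shape[0])
    b[-1] = 1.0
    for j in range(n):
        b[:-1] = delta * X[:, j]
        a, _ = nnls(A, b)
        s = a.sum()
        out[:, j] = a / s if s > 0 else 1.0 / k
    return out


def align_endmembers(estimated: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Column permutation of ``estimated`` best matching ``reference``.

    Hungarian assignment on the pairwise spectral-angle matrix; returns
    the permutation ``perm`` such that ``estimated[:, perm[j]]`` matches
    ``reference[:, j]``.
    """
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("endmember matrices must share a shape for alignment")
    k = ref.shape[1]
    cost = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            cost[i, j] = spectral_angle(ref[:, i], est[:, j])
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    return perm
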