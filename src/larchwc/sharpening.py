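"""Consistency-constrained sharpening of 20 m bands to the 10 m grid.

Sentinel-2's red-edge and SWIR bands are delivered at 20 m while the
visible/NIR quartet is at 10 m.  This module transfers the spatial
detail of the 10 m bands into the 20 m bands with a local linear
regression: per low-resolution window, the 20 m band is regressed on
block-averaged 10 m bands, the fit is applied at 10 m, and (by default)
the block-wise residual is added back so that every 2x2 block mean of
the output reproduces the 20 m input exactly.

This is a deliberately simple, testable sharpener with an explicit
consistency contract — a stand-in for heavier multi-band
super-resolution tools that share geometric detail across bands while
preserving each band's radiometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from larchwc.scene import (
    BANDS_10M,
    SpectralScene,
    block_mean,
    block_replicate,
)

__all__ = ["SharpenConfig", "sharpen_band", "sharpen_scene"]


@dataclass(frozen=True)
class SharpenConfig:
    """Sharpener parameters.

    window
        Local regression window, in 10 m cells; must be odd and >= 3.
    ridge
        Tikhonov weight on the regression slopes; avoids singular fits in
        radiometrically flat areas.
    consistency
        Add back the upsampled block residual so 2x2 block means of the
        output equal the 20 m input exactly.
    """

    window: int = 15
    ridge: float = 1e-3
    consistency: bool = True

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")


def sharpen_band(
    low_band: np.ndarray,
    high_bands: list[np.ndarray],
    config: SharpenConfig | None = None,
) -> np.ndarray:
    """Predict one 20 m band at 10 m from the 10 m bands.

    ``low_band`` must be exactly the 2x2 block-aggregation grid of the
    high-resolution extent.
    """
    config = config or SharpenConfig()
    low = np.asarray(low_band, dtype=np.float64)
    highs = [np.asarray(h, dtype=np.float64) for h in high_bands]
    if not highs:
        raise ValueError("at least one 10 m band is required")
    H, W = highs[0].shape
    if any(h.shape != (H, W) for h in highs):
        raise ValueError("all 10 m bands must share one grid")
    if low.shape != (H // 2, W // 2) or H % 2 or W % 2:
        raise ValueError(
            f"low band shape {low.shape} is not the 2x2 aggregation of {(H, W)}"
        )

    hb = np.stack([block_mean(h, 2) for h in highs])          # (p, h, w) at 20 m
    hi = np.stack(highs)                                      # (p, H, W) at 10 m
    p = hb.shape[0]
    h2, w2 = low.shape

    # Window radius in low-resolution cells (window is given in 10 m cells).
    r = max(1, (config.window // 2) // 2)

    pred10 = np.empty((H, W))
    for i in range(h2):
        i0, i1 = max(0, i - r), min(h2, i + r + 1)
        for j in range(w2):
            j0, j1 = max(0, j - r), min(w2, j + r + 1)
            Xw = hb[:, i0:i1, j0:j1].reshape(p, -1).T          # (n, p)
            yw = low[i0:i1, j0:j1].ravel()
            n = Xw.shape[0]
            A = np.column_stack([np.ones(n), Xw])
            AtA = A.T @ A
            AtA[1:, 1:] += config.ridge * np.eye(p)            # ridge on slopes only
            beta = np.linalg.solve(AtA, A.T @ yw)
            block = hi[:, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2].reshape(p, -1)
            pred10[2 * i : 2 * i + 2, 2 * j : 2 * j + 2] = (
                beta[0] + beta[1:] @ block
            ).reshape(2, 2)

    if config.consistency:
        residual = low - block_mean(pred10, 2)
        pred10 = pred10 + block_replicate(residual, 2)
    return pred10


def sharpen_scene(scene: SpectralScene, config: SharpenConfig | None = None) -> SpectralScene:
    """Return the scene with every band on the 10 m grid.

    Native 10 m bands pass through unchanged; each 20 m band is sharpened
    against all available 10 m bands.
    """
    config = config or SharpenConfig()
    high_names = [b for b in scene.band_names if scene.gsd[b] == 10.0]
    if not high_names:
        raise ValueError("sharpening requires at least one native 10 m band")
    highs = [scene.bands[b] for b in high_names]
    out_bands: dict[str, np.ndarray] = {}
    out_gsd: dict[str, float] = {}
    for name in scene.band_names:
        if scene.gsd[name] == 10.0:
            out_bands[name] = scene.bands[name].copy()
        else:
            out_bands[name] = sharpen_band(scene.bands[name], highs, config)
        out_gsd[name] = 10.0
    return SpectralScene(
        bands=out_bands, transform=scene.transform, gsd=out_gsd, nodata=scene.nodata
    )
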