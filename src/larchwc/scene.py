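"""The multiband reflectance scene container.

Sentinel-2 delivers the ten bands used for vegetation monitoring at two
ground sampling distances: the visible/NIR quartet (B2, B3, B4, B8) at
10 m and the red-edge/narrow-NIR/SWIR sextet (B5, B6, B7, B8A, B11,
B12) at 20 m.  A :class:`SpectralScene` holds per-band 2-D reflectance
grids that share one georeferenced origin but may differ in resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from larchwc.geo import Affine

#: 10 m native bands (blue, green, red, NIR).
BANDS_10M: tuple[str, ...] = ("B2", "B3", "B4", "B8")
#: 20 m native bands (red edge x3, narrow NIR, SWIR x2).
BANDS_20M: tuple[str, ...] = ("B5", "B6", "B7", "B8A", "B11", "B12")
#: All bands, in wavelength order.
ALL_BANDS: tuple[str, ...] = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12")

#: Central wavelength (nm) of each band, for plotting and CSV export.
BAND_WAVELENGTHS_NM: dict[str, int] = {
    "B2": 490, "B3": 560, "B4": 665, "B5": 705, "B6": 740,
    "B7": 783, "B8": 842, "B8A": 865, "B11": 1610, "B12": 2190,
}

NATIVE_GSD: dict[str, float] = {b: 10.0 for b in BANDS_10M} | {b: 20.0 for b in BANDS_20M}

DEFAULT_NODATA = -9999.0


class UnknownBandError(ValueError):
    """Raised when a band name outside the supported ten is encountered."""

    def __init__(self, name: str):
        super().__init__(
            f"unknown band {name!r}; accepted band names are {', '.join(ALL_BANDS)}"
        )
        self.band = name


@dataclass
class SpectralScene:
    """Georeferenced stack of named reflectance bands, possibly mixed-resolution.

    Parameters
    ----------
    bands
        Mapping band name -> 2-D float array of surface reflectance.
    transform
        Affine georeference of the *10 m* grid.  Bands with gsd 20 share the
        same origin with doubled cell size.
    gsd
        Mapping band name -> ground sampling distance in metres (10 or 20).
    nodata
        Sentinel value marking invalid cells.
    """

    bands: dict[str, np.ndarray]
    transform: Affine
    gsd: dict[str, float] = field(default_factory=dict)
    nodata: float = DEFAULT_NODATA

    def __post_init__(self):
        for name in self.bands:
            if name not in ALL_BANDS:
                raise UnknownBandError(name)
        if not self.gsd:
            self.gsd = {name: NATIVE_GSD[name] for name in self.bands}
        for name, g in self.gsd.items():
            if g not in (10.0, 20.0, 10, 20):
                raise ValueError(f"gsd for band {name} must be 10 or 20 m, got {g}")

    @property
    def band_names(self) -> list[str]:
        return [b for b in ALL_BANDS if b in self.bands]

    def shape_at(self, gsd: float) -> tuple[int, int]:
        """(rows, cols) of the grid at the requested resolution."""
        for name, g in self.gsd.items():
            if g == gsd:
                return self.bands[name].shape
        raise ValueError(f"scene has no band at {gsd} m")

    @property
    def is_uniform_10m(self) -> bool:
        return all(g == 10.0 for g in self.gsd.values())

    def pixel_vector(self, row: int, col: int, bands: list[str] | None = None) -> np.ndarray:
        """Spectrum of one 10 m cell; requires a uniform 10 m scene."""
        if not self.is_uniform_10m:
            raise ValueError("pixel_vector requires an all-10 m scene; sharpen first")
        names = bands or self.band_names
        return np.array([self.bands[b][row, col] for b in names])

    def stack(self, bands: list[str] | None = None) -> np.ndarray:
        """(n_bands, rows, cols) array; requires a uniform 10 m scene."""
        if not self.is_uniform_10m:
            raise ValueError("stack requires an all-10 m scene; sharpen first")
        names = bands or self.band_names
        return np.stack([self.bands[b] for b in names])


def block_mean(grid: np.ndarray, factor: int = 2) -> np.ndarray:
    """Aggregate a grid by ``factor``x``factor`` block averaging.

    The grid extent must be an exact multiple of ``factor`` in both axes —
    the fixed relationship between the 10 m and 20 m Sentinel-2 grids.
    """
    h, w = grid.shape
    if h % factor or w % factor:
        raise ValueError(f"grid shape {grid.shape} is not a multiple of {factor}")
    return grid.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def block_replicate(grid: np.ndarray, factor: int = 2) -> np.ndarray:
    """Inverse of :func:`block_mean` up to averaging: nearest upsampling."""
    return np.kron(grid, np.ones((factor, factor), dtype=grid.dtype))
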