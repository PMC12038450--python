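"""Minimal affine georeferencing for axis-aligned north-up rasters.

Coordinates follow the usual geospatial raster convention: row-major
grids, origin at the top-left corner, pixel-centre sampling, y
decreasing with row index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Affine"]


@dataclass(frozen=True)
class Affine:
    """2-D affine map from (col, row) pixel space to world (x, y).

    ``x = a*col + b*row + c`` and ``y = d*col + e*row + f``, matching the
    coefficient order used by GDAL-style libraries.  Only axis-aligned
    transforms (b == d == 0) are produced by this package, but the general
    form is kept for fidelity with the GeoTIFF model.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def from_origin(cls, west: float, north: float, xsize: float, ysize: float) -> "Affine":
        """Transform for a grid whose top-left corner is (west, north)."""
        return cls(xsize, 0.0, west, 0.0, -ysize, north)

    def __mul__(self, colrow) -> tuple[float, float]:
        col, row = colrow
        return (
            self.a * col + self.b * row + self.c,
            self.d * col + self.e * row + self.f,
        )

    def xy(self, row, col, offset: str = "center"):
        """World coordinates of a pixel; ``offset='center'`` or ``'ul'``."""
        shift = 0.5 if offset == "center" else 0.0
        col = np.asarray(col, dtype=float) + shift
        row = np.asarray(row, dtype=float) + shift
        return (
            self.a * col + self.b * row + self.c,
            self.d * col + self.e * row + self.f,
        )

    def rowcol(self, x, y) -> tuple:
        """Integer (row, col) of the cell containing (x, y); half-open cells."""
        if self.b != 0 or self.d != 0:
            raise ValueError("rowcol only supports axis-aligned transforms")
        col = np.floor((np.asarray(x, dtype=float) - self.c) / self.a).astype(int)
        row = np.floor((np.asarray(y, dtype=float) - self.f) / self.e).astype(int)
        return row, col

    def scaled(self, factor: float) -> "Affine":
        """Same origin, cell size multiplied by ``factor`` (e.g. 2 for 20 m)."""
        return Affine(self.a * factor, self.b, self.c, self.d, self.e * factor, self.f)

    def to_gdal(self) -> tuple[float, float, float, float, float, float]:
        return (self.c, self.a, self.b, self.f, self.d, self.e)

    def almost_equals(self, other: "Affine", tol: float = 1e-9) -> bool:
        return all(
            abs(p - q) <= tol
            for p, q in zip(
                (self.a, self.b, self.c, self.d, self.e, self.f),
                (other.a, other.b, other.c, other.d, other.e, other.f),
            )
        )
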