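"""Reading and writing scenes, masks and plot tables.

Scenes are stored as a pair of multiband GeoTIFFs — ``stack10m.tif`` for
the native 10 m bands and ``stack20m.tif`` for the 20 m bands — inside
one scene directory, with band names in the image description and the
georeference in standard GeoTIFF ModelPixelScale/ModelTiepoint tags.
Plot tables are UTF-8 comma-separated CSV with a ``.`` decimal point.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from larchwc.geo import Affine
from larchwc.scene import ALL_BANDS, DEFAULT_NODATA, SpectralScene, UnknownBandError

__all__ = [
    "read_scene",
    "write_scene",
    "read_raster",
    "write_raster",
    "raster_to_points",
    "read_plot_table",
    "write_plot_table",
    "PLOT_TABLE_COLUMNS",
]

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922

PLOT_TABLE_COLUMNS = ("plot_id", "x", "y", "tree_id", "FW_g", "DW_g", "LWCF", "LWCD", "LLR")


def _geotags(transform: Affine):
    return [
        (_MODEL_PIXEL_SCALE, "d", 3, (abs(transform.a), abs(transform.e), 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform.c, transform.f, 0.0)),
    ]


def write_raster(
    path: str | Path,
    data: np.ndarray,
    transform: Affine,
    band_names: list[str] | None = None,
    nodata: float = DEFAULT_NODATA,
    meta: dict | None = None,
) -> Path:
    """Write a (bands, rows, cols) or (rows, cols) array as a GeoTIFF."""
    path = Path(path)
    arr = np.asarray(data)
    if arr.ndim == 2:
        arr = arr[None]
    desc = {
        "bands": band_names if band_names is not None else [f"band{i+1}" for i in range(arr.shape[0])],
        "nodata": nodata,
        "gsd": abs(transform.a),
    }
    if meta:
        desc.update(meta)
    tifffile.imwrite(
        path,
        arr.astype(np.float32),
        photometric="minisblack",
        description=json.dumps(desc),
        metadata=None,
        extratags=_geotags(transform),
    )
    return path


def read_raster(path: str | Path):
    """Read a GeoTIFF written by :func:`write_raster`.

    Returns ``(data, transform, description_dict)`` with ``data`` of shape
    (bands, rows, cols), float32.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        page = tif.pages[0]
        desc = page.description
        scale_tag = page.tags.get(_MODEL_PIXEL_SCALE)
        tie_tag = page.tags.get(_MODEL_TIEPOINT)
    if scale_tag is None or tie_tag is None:
        raise ValueError(f"{path} has no GeoTIFF georeference tags")
    sx, sy, _ = scale_tag.value[:3]
    west, north = tie_tag.value[3], tie_tag.value[4]
    transform = Affine.from_origin(west, north, sx, sy)
    if data.ndim == 2:
        data = data[None]
    try:
        meta = json.loads(desc) if desc else {}
    except json.JSONDecodeError:
        meta = {}
    return data.astype(np.float32), transform, meta


def write_scene(scene: SpectralScene, directory: str | Path) -> Path:
    """Write a scene directory with separate 10 m and 20 m stacks."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names10 = [b for b in scene.band_names if scene.gsd[b] == 10.0]
    names20 = [b for b in scene.band_names if scene.gsd[b] == 20.0]
    if names10:
        write_raster(
            directory / "stack10m.tif",
            np.stack([scene.bands[b] for b in names10]),
            scene.transform,
            band_names=names10,
            nodata=scene.nodata,
        )
    if names20:
        write_raster(
            directory / "stack20m.tif",
            np.stack([scene.bands[b] for b in names20]),
            scene.transform.scaled(2.0),
            band_names=names20,
            nodata=scene.nodata,
        )
    return directory


def read_scene(path: str | Path) -> SpectralScene:
    """Read a scene directory produced by :func:`write_scene`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    bands: dict[str, np.ndarray] = {}
    gsd: dict[str, float] = {}
    transform = None
    nodata = DEFAULT_NODATA
    found = False
    for fname, res in (("stack10m.tif", 10.0), ("stack20m.tif", 20.0)):
        f = path / fname
        if not f.exists():
            continue
        found = True
        data, tr, meta = read_raster(f)
        names = meta.get("bands", [])
        if len(names) != data.shape[0]:
            raise ValueError(f"{f}: band-name list does not match band count")
        for name, grid in zip(names, data):
            if name not in ALL_BANDS:
                raise UnknownBandError(name)
            bands[name] = grid.astype(np.float64)
            gsd[name] = res
        nodata = meta.get("nodata", nodata)
        if res == 10.0:
            transform = tr
        elif transform is None:
            transform = Affine.from_origin(tr.c, tr.f, abs(tr.a) / 2.0, abs(tr.e) / 2.0)
    if not found:
        raise FileNotFoundError(f"no stack10m.tif / stack20m.tif under {path}")
    return SpectralScene(bands=bands, transform=transform, gsd=gsd, nodata=nodata)


def raster_to_points(mask: np.ndarray, scene: SpectralScene) -> pd.DataFrame:
    """One point per true mask cell, at the 10 m cell centres.

    Mirrors the raster -> point conversion used to turn a forest mask into
    a table of pixel locations for feature extraction.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != scene.shape_at(10.0):
        raise ValueError(
            f"mask shape {mask.shape} is not aligned with the scene's 10 m grid "
            f"{scene.shape_at(10.0)}"
        )
    rows, cols = np.where(mask)
    x, y = scene.transform.xy(rows, cols, offset="center")
    return pd.DataFrame({"x": x, "y": y, "row": rows, "col": cols})


def write_plot_table(records: pd.DataFrame, path: str | Path) -> Path:
    """Write the per-tree plot table as CSV (UTF-8, comma, '.' decimal)."""
    missing = [c for c in PLOT_TABLE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"plot table is missing required column(s): {', '.join(missing)}")
    path = Path(path)
    records.to_csv(path, index=False, encoding="utf-8", float_format="%.12g")
    return path


def read_plot_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in PLOT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing required column(s): {', '.join(missing)}")
    return df


def mosaic(scenes: list[SpectralScene]) -> SpectralScene:
    """Overlay scenes on a shared grid, last write wins.

    All scenes must share cell size and band set; extents may differ in
    origin by whole cells.  Used to merge adjacent acquisitions into one
    working scene.
    """
    if not scenes:
        raise ValueError("mosaic of zero scenes")
    ref = scenes[0]
    names = ref.band_names
    xs, ys, xe, ye = [], [], [], []
    for s in scenes:
        if s.band_names != names:
            raise ValueError("scenes must share the same band set")
        h, w = s.shape_at(10.0)
        xs.append(s.transform.c)
        ys.append(s.transform.f - h * 10.0)
        xe.append(s.transform.c + w * 10.0)
        ye.append(s.transform.f)
    west, south, east, north = min(xs), min(ys), max(xe), max(ye)
    W = int(round((east - west) / 10.0))
    H = int(round((north - south) / 10.0))
    W += W % 2
    H += H % 2
    out_tr = Affine.from_origin(west, south + H * 10.0, 10.0, 10.0)
    out_bands = {}
    for name in names:
        res = ref.gsd[name]
        f = int(res // 10)
        grid = np.full((H // f, W // f), ref.nodata, dtype=np.float64)
        for s in scenes:
            r0 = int(round((out_tr.f - s.transform.f) / res))
            c0 = int(round((s.transform.c - out_tr.c) / res))
            g = s.bands[name]
            grid[r0 : r0 + g.shape[0], c0 : c0 + g.shape[1]] = g
        out_bands[name] = grid
    return SpectralScene(bands=out_bands, transform=out_tr, gsd=dict(ref.gsd), nodata=ref.nodata)
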