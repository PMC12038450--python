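"""Registry of the 40 multispectral vegetation indices and batch evaluation.

Each index is registered with the formula string as printed in the
source index table, a machine-evaluable expression, and a provenance
flag.  Where the printed formula is typographically garbled (lost
superscripts rendered like ``B82``/``B80.5``, lost parentheses or
division bars), the canonical literature form is substituted and both
forms are kept; every such interpretation is recorded in the entry's
notes.  Indices whose printed arithmetic is well-formed are evaluated
exactly as printed, even where the form is unusual (e.g. SCCI, whose
printed expression algebraically reduces to ``100 * (B8 + B4)``).

Undefined values (division by zero, negative radicand) are returned as
NaN together with an explicit reason — never as silent NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VIDef",
    "FeatureTable",
    "registry",
    "registry_names",
    "compute_index",
    "evaluate_index",
    "compute_feature_table",
]


@dataclass(frozen=True)
class VIDef:
    """One vegetation-index definition."""

    name: str
    printed_formula: str
    provenance: str  # "as_printed" | "canonical_substituted"
    func: callable = field(repr=False)
    canonical_formula: str | None = None
    notes: str = ""
    requires: tuple[str, ...] = ()


class _Ctx:
    """Collects reasons for undefined values during evaluation."""

    def __init__(self):
        self.reasons: list[str] = []


def _div(ctx: _Ctx, num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    bad = den == 0
    if np.any(bad):
        ctx.reasons.append("division by zero")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, num / np.where(bad, 1.0, den))
    return out


def _sqrt(ctx: _Ctx, x):
    x = np.asarray(x, dtype=float)
    bad = x < 0
    if np.any(bad):
        ctx.reasons.append("negative radicand")
    return np.where(bad, np.nan, np.sqrt(np.where(bad, 0.0, x)))


def _ndvi(ctx: _Ctx, b):
    return _div(ctx, b["B8"] - b["B4"], b["B8"] + b["B4"])


def _entries() -> list[VIDef]:
    E = []

    def add(name, printed, func, requires, provenance="as_printed", canonical=None, notes=""):
        E.append(VIDef(
            name=name, printed_formula=printed, provenance=provenance,
            func=func, canonical_formula=canonical, notes=notes,
            requires=tuple(requires),
        ))

    add("ARI2", "(B8/B3)-(B8/B5)",
        lambda b, c: _div(c, b["B8"], b["B3"]) - _div(c, b["B8"], b["B5"]),
        ["B8", "B3", "B5"])
    add("CCRI", "B4/B5", lambda b, c: _div(c, b["B4"], b["B5"]), ["B4", "B5"])
    add("CRI1", "(1/B2)-(1/B3)",
        lambda b, c: _div(c, 1.0, b["B2"]) - _div(c, 1.0, b["B3"]),
        ["B2", "B3"])
    add("CTVI", "(NDVI+0.5|NDVI+0.5|)x|NDVI+0.5|",
        lambda b, c: (lambda t: _div(c, t, np.abs(t)) * _sqrt(c, np.abs(t)))(_ndvi(c, b) + 0.5),
        ["B8", "B4"],
        provenance="canonical_substituted",
        canonical="((NDVI+0.5)/|NDVI+0.5|)*sqrt(|NDVI+0.5|)",
        notes="printed form lost the division bar and square root; canonical "
              "corrected transformed NDVI substituted")
    add("DSWI-4", "B3/B4", lambda b, c: _div(c, b["B3"], b["B4"]), ["B3", "B4"])
    add("EVI", "2.5x(B8-B4)/(B8+6xB4-7.5xB2+1)",
        lambda b, c: 2.5 * _div(c, b["B8"] - b["B4"], b["B8"] + 6 * b["B4"] - 7.5 * b["B2"] + 1),
        ["B8", "B4", "B2"])
    add("EVI2", "2.5x(B8-B4)/(B8+2.4xB4+1)",
        lambda b, c: 2.5 * _div(c, b["B8"] - b["B4"], b["B8"] + 2.4 * b["B4"] + 1),
        ["B8", "B4"])
    add("GNDVI", "(B8-B3)/(B8+B3)",
        lambda b, c: _div(c, b["B8"] - b["B3"], b["B8"] + b["B3"]), ["B8", "B3"])
    add("MNLI", "1.5(B80.5-B4)/(B80.5+B4+0.5)",
        lambda b, c: 1.5 * _div(c, b["B8"] ** 2 - b["B4"], b["B8"] ** 2 + b["B4"] + 0.5),
        ["B8", "B4"],
        provenance="canonical_substituted",
        canonical="1.5*(B8^2-B4)/(B8^2+B4+0.5)",
        notes="printed superscript garbled to 'B80.5'; the modified non-linear "
              "index uses the squared NIR band, so B8^2 substituted")
    add("MSRreg", "(B8/B5-1)/(B8/B5+1)",
        lambda b, c: _div(c, _div(c, b["B8"], b["B5"]) - 1, _div(c, b["B8"], b["B5"]) + 1),
        ["B8", "B5"])
    add("NDGI", "(B3-B4)/(B3+B4)",
        lambda b, c: _div(c, b["B3"] - b["B4"], b["B3"] + b["B4"]), ["B3", "B4"])
    add("NDI45", "(B5-B4)/(B5+B4)",
        lambda b, c: _div(c, b["B5"] - b["B4"], b["B5"] + b["B4"]), ["B5", "B4"])
    add("NDII", "(B8-B12)/(B8+B12)",
        lambda b, c: _div(c, b["B8"] - b["B12"], b["B8"] + b["B12"]), ["B8", "B12"])
    add("NDMI", "(B8-B11)/(B8+B11)",
        lambda b, c: _div(c, b["B8"] - b["B11"], b["B8"] + b["B11"]), ["B8", "B11"])
    add("NDVI", "(B8-B4)/(B8+B4)", lambda b, c: _ndvi(c, b), ["B8", "B4"])
    add("NDREI", "(B8-B6)/(B8+B6)",
        lambda b, c: _div(c, b["B8"] - b["B6"], b["B8"] + b["B6"]), ["B8", "B6"],
        notes="evaluated from the sharpened B6 red-edge band")
    add("NDVIreg", "(B8-B5)/(B8+B5)",
        lambda b, c: _div(c, b["B8"] - b["B5"], b["B8"] + b["B5"]), ["B8", "B5"],
        notes="identical printed formula to RDVIreg and red_edge_ndvi")
    add("NLI", "(B82-B4)/(B82+B4)",
        lambda b, c: _div(c, b["B8"] ** 2 - b["B4"], b["B8"] ** 2 + b["B4"]),
        ["B8", "B4"],
        notes="printed 'B82' read as the lost superscript B8^2 (non-linear index)")
    add("OSAVI", "(B8-B5)/(B8+B5+0.16)",
        lambda b, c: _div(c, b["B8"] - b["B5"], b["B8"] + b["B5"] + 0.16), ["B8", "B5"],
        notes="printed with B5 while OSAVIreg prints B4 — plausibly swapped; "
              "implemented as printed")
    add("OSAVIreg", "(1+0.16)(B8-B4)/(B8+B4+0.16)",
        lambda b, c: 1.16 * _div(c, b["B8"] - b["B4"], b["B8"] + b["B4"] + 0.16),
        ["B8", "B4"],
        notes="printed with B4 while OSAVI prints B5 — plausibly swapped; "
              "implemented as printed")
    add("PSSR", "B8/B4", lambda b, c: _div(c, b["B8"], b["B4"]), ["B8", "B4"])
    add("RDVIreg", "(B8-B5)/(B8+B5)",
        lambda b, c: _div(c, b["B8"] - b["B5"], b["B8"] + b["B5"]), ["B8", "B5"],
        notes="identical printed formula to NDVIreg and red_edge_ndvi")
    add("RVIreg", "B8/B5", lambda b, c: _div(c, b["B8"], b["B5"]), ["B8", "B5"])
    add("SAVI", "1.5x(B8-B4)/(B8+B4+0.5)",
        lambda b, c: 1.5 * _div(c, b["B8"] - b["B4"], b["B8"] + b["B4"] + 0.5),
        ["B8", "B4"])
    add("SIWSI", "B8a-B11/B8a+B11",
        lambda b, c: _div(c, b["B8A"] - b["B11"], b["B8A"] + b["B11"]), ["B8A", "B11"],
        provenance="canonical_substituted",
        canonical="(B8A-B11)/(B8A+B11)",
        notes="printed form lost its parentheses; the name (normalized "
              "difference 860/1640) fixes the canonical form")
    add("VGCI", "(B8-B4)/B4",
        lambda b, c: _div(c, b["B8"] - b["B4"], b["B4"]), ["B8", "B4"])
    add("AFRI1600", "B8-0.66[B11/(B8+0.66xB11)]",
        lambda b, c: _div(c, b["B8"] - 0.66 * b["B11"], b["B8"] + 0.66 * b["B11"]),
        ["B8", "B11"],
        provenance="canonical_substituted",
        canonical="(B8-0.66*B11)/(B8+0.66*B11)",
        notes="printed bracket placement garbled; canonical aerosol-free index "
              "ratio substituted")
    add("AFRI2100", "B8-0.5[B12/(B8+0.56xB12)]",
        lambda b, c: _div(c, b["B8"] - 0.5 * b["B12"], b["B8"] + 0.5 * b["B12"]),
        ["B8", "B12"],
        provenance="canonical_substituted",
        canonical="(B8-0.5*B12)/(B8+0.5*B12)",
        notes="printed brackets and the inconsistent 0.5/0.56 coefficients "
              "garbled; canonical form with 0.5 substituted")
    add("DVI", "B8-B4", lambda b, c: b["B8"] - b["B4"] + 0.0, ["B8", "B4"])
    add("DVIreg", "B8-B5", lambda b, c: b["B8"] - b["B5"] + 0.0, ["B8", "B5"])
    add("Int2", "(B3+B4+B5)/2",
        lambda b, c: (b["B3"] + b["B4"] + b["B5"]) / 2.0, ["B3", "B4", "B5"])
    add("SI1", "B5xB4", lambda b, c: b["B5"] * b["B4"] + 0.0, ["B5", "B4"])
    add("GMNLI", "1.5(B80.5-B3)/(B80.5+B3+0.5)",
        lambda b, c: 1.5 * _div(c, _sqrt(c, b["B8"]) - b["B3"], _sqrt(c, b["B8"]) + b["B3"] + 0.5),
        ["B8", "B3"],
        notes="printed 'B80.5' read as the lost superscript B8^0.5")
    add("SIreg", "B2+B5", lambda b, c: b["B2"] + b["B5"] + 0.0, ["B2", "B5"])
    add("MTVI2", "1.5[1.2(B8-B3)-2.5(B4-B3)](2B8+1)2-(6B8-5B40.5)-0.5",
        lambda b, c: _div(
            c,
            1.5 * (1.2 * (b["B8"] - b["B3"]) - 2.5 * (b["B4"] - b["B3"])),
            _sqrt(c, (2 * b["B8"] + 1) ** 2 - (6 * b["B8"] - 5 * _sqrt(c, b["B4"])) - 0.5),
        ),
        ["B8", "B3", "B4"],
        provenance="canonical_substituted",
        canonical="1.5*[1.2*(B8-B3)-2.5*(B4-B3)] / sqrt((2*B8+1)^2-(6*B8-5*sqrt(B4))-0.5)",
        notes="printed form lost the division bar, square root and "
              "superscripts; canonical modified triangular index substituted")
    add("GDVI", "B8-B3", lambda b, c: b["B8"] - b["B3"] + 0.0, ["B8", "B3"])
    add("NLI2", "(B82-B3)/(B82+B3)",
        lambda b, c: _div(c, b["B8"] ** 2 - b["B3"], b["B8"] ** 2 + b["B3"]),
        ["B8", "B3"],
        notes="printed 'B82' read as the lost superscript B8^2")
    add("CIreg", "B8/B5-1", lambda b, c: _div(c, b["B8"], b["B5"]) - 1.0, ["B8", "B5"])
    add("SCCI", "100x(B8-B4)/NDVI",
        lambda b, c: 100.0 * _div(c, b["B8"] - b["B4"], _ndvi(c, b)),
        ["B8", "B4"],
        notes="evaluated as printed; algebraically reduces to 100*(B8+B4); "
              "undefined where NDVI = 0")
    add("red_edge_ndvi", "(B8-B5)/(B8+B5)",
        lambda b, c: _div(c, b["B8"] - b["B5"], b["B8"] + b["B5"]), ["B8", "B5"],
        notes="identical printed formula to NDVIreg and RDVIreg")
    return E


_REGISTRY: list[VIDef] = _entries()
_BY_NAME: dict[str, VIDef] = {d.name: d for d in _REGISTRY}
assert len(_BY_NAME) == len(_REGISTRY), "duplicate index names in registry"


def registry() -> list[VIDef]:
    """All 40 vegetation-index definitions, in table order."""
    return list(_REGISTRY)


def registry_names() -> list[str]:
    return [d.name for d in _REGISTRY]


def registry_as_json() -> list[dict]:
    """Serializable registry export (name, formulas, provenance, notes)."""
    return [
        {
            "name": d.name,
            "printed_formula": d.printed_formula,
            "canonical_formula": d.canonical_formula,
            "provenance": d.provenance,
            "notes": d.notes,
            "requires": list(d.requires),
        }
        for d in _REGISTRY
    ]


def evaluate_index(name: str, bands: dict):
    """Evaluate one index; returns ``(value, reason)``.

    ``value`` is a float (or array) with NaN where undefined; ``reason``
    is None when fully defined, else a short explanation.
    """
    if name not in _BY_NAME:
        raise KeyError(f"unknown vegetation index {name!r}")
    d = _BY_NAME[name]
    missing = [b for b in d.requires if b not in bands]
    if missing:
        raise KeyError(f"index {name} requires band(s) {', '.join(missing)}")
    ctx = _Ctx()
    value = d.func(bands, ctx)
    reason = "; ".join(dict.fromkeys(ctx.reasons)) or None
    if np.ndim(value) == 0:
        value = float(value)
        if not np.isfinite(value) and reason is None:
            reason = "non-finite result"
    return value, reason


def compute_index(name: str, bands: dict):
    """Value of one index on a band mapping (NaN where undefined)."""
    return evaluate_index(name, bands)[0]


@dataclass
class FeatureTable:
    """Vegetation-index features per plot or pixel, plus a target column.

    ``data`` holds the numeric values (NaN where undefined); ``flags``
    holds, for every NaN, the reason it is missing ("" elsewhere), so no
    NaN is ever silent.
    """

    data: pd.DataFrame
    flags: pd.DataFrame

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c in _BY_NAME]


def compute_feature_table(
    scene,
    plots: pd.DataFrame | None = None,
    mask: np.ndarray | None = None,
    abundance: np.ndarray | None = None,
    min_abundance: float = 0.5,
) -> FeatureTable:
    """Evaluate all 40 indices per plot (mean over its cells) or per pixel.

    Parameters
    ----------
    scene
        An all-10 m :class:`~larchwc.scene.SpectralScene`.
    plots
        Table with ``plot_id``, ``row``, ``col`` columns (one row per plot
        cell); output has one row per plot, cell-mean index values.
    mask
        Alternative to ``plots``: boolean raster; output has one row per
        true cell.
    abundance
        Optional vegetation-abundance raster; cells below
        ``min_abundance`` are excluded (mixed-pixel filter).  A plot whose
        cells are all excluded yields a flagged missing row.
    """
    if not scene.is_uniform_10m:
        raise ValueError("feature extraction requires an all-10 m scene; sharpen first")
    if (plots is None) == (mask is None):
        raise ValueError("provide exactly one of plots= or mask=")
    h, w = scene.shape_at(10.0)

    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        rows, cols = np.where(mask)
        ids = np.arange(rows.size)
        groups = pd.DataFrame({"plot_id": ids, "row": rows, "col": cols})
    else:
        groups = plots[["plot_id", "row", "col"]].copy()

    inside = (groups["row"] >= 0) & (groups["row"] < h) & (groups["col"] >= 0) & (groups["col"] < w)
    kept = groups[inside].copy()
    if abundance is not None:
        ab = np.asarray(abundance, dtype=float)
        if ab.shape != (h, w):
            raise ValueError("abundance raster is not aligned with the scene")
        ok = ab[kept["row"].to_numpy(), kept["col"].to_numpy()] >= min_abundance
        filtered = kept[~ok]
        kept = kept[ok]
    else:
        filtered = kept.iloc[0:0]

    r = kept["row"].to_numpy()
    c = kept["col"].to_numpy()
    bands = {name: scene.bands[name][r, c] for name in scene.band_names}

    values = {}
    cellflags = {}
    for d in _REGISTRY:
        v, _ = evaluate_index(d.name, bands)
        v = np.asarray(v, dtype=float)
        values[d.name] = v
        cellflags[d.name] = ~np.isfinite(v)

    out_rows = []
    out_flags = []
    all_ids = pd.unique(groups["plot_id"])
    kept_ids = kept["plot_id"].to_numpy()
    for pid in all_ids:
        sel = kept_ids == pid
        row_vals: dict = {"plot_id": pid}
        row_flags: dict = {"plot_id": pid}
        if not sel.any():
            if pid in set(filtered["plot_id"]):
                why = f"all cells below vegetation abundance {min_abundance}"
            else:
                why = "plot cell outside the scene extent"
            for d in _REGISTRY:
                row_vals[d.name] = np.nan
                row_flags[d.name] = why
        else:
            for d in _REGISTRY:
                v = values[d.name][sel]
                good = np.isfinite(v)
                if good.any():
                    row_vals[d.name] = float(v[good].mean())
                    row_flags[d.name] = ""
                else:
                    row_vals[d.name] = np.nan
                    row_flags[d.name] = "undefined on every plot cell"
        out_rows.append(row_vals)
        out_flags.append(row_flags)

    data = pd.DataFrame(out_rows).set_index("plot_id")
    flags = pd.DataFrame(out_flags).set_index("plot_id")
    return FeatureTable(data=data, flags=flags)
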