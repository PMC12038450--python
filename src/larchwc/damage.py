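"""Field formulas, severity classification and damage mapping.

Needle water content is expressed two ways from a fresh/dry weighing of
a needle sample:

    LWCF = (FW - DW) / FW      (water as a fraction of fresh mass, in [0, 1))
    LWCD = (FW - DW) / DW      (water relative to dry mass, can exceed 1)

which are linked by the identity LWCD = LWCF / (1 - LWCF).  The leaf
loss rate LLR = N_lost / (N_healthy + N_lost) is the field severity
indicator, averaged branch -> tree -> plot.  All three scales carry a
four-level severity scheme (healthy / light / moderate / severe); the
fractions are stored on the raw scale, percent being display formatting
only.

Note the published healthy thresholds LWCF > 0.7 and LWCD > 2.1 are
mutually inconsistent under the identity (0.7 maps to 2.333); both are
kept as printed, independently per scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from larchwc.metrics import ConfusionSummary, confusion_summary

__all__ = [
    "SEVERITY_CLASSES",
    "SeverityScheme",
    "LWCF_SCHEME",
    "LWCD_SCHEME",
    "LLR_SCHEME",
    "lwc_from_weights",
    "llr",
    "classify_severity",
    "map_damage",
    "confusion",
]

#: Ordered severity legend (integer code = list position).
SEVERITY_CLASSES: tuple[str, ...] = ("healthy", "light", "moderate", "severe")


@dataclass(frozen=True)
class SeverityScheme:
    """Four-level severity classification on one scale.

    ``direction='decreasing'`` means lower values are more severe (the
    water-content scales); ``'increasing'`` means higher values are more
    severe (the leaf-loss scale).  ``bounds`` are the three class edges
    ordered from the healthy side: for decreasing scales
    (healthy|light, light|moderate, moderate|severe) with the closures

        severe < b2 <= moderate < b1 <= light <= b0 < healthy,

    and for increasing scales

        healthy <= b0 < light <= b1 < moderate <= b2 < severe.
    """

    scale: str
    direction: str
    bounds: tuple[float, float, float]
    classes: tuple[str, ...] = SEVERITY_CLASSES

    def __post_init__(self):
        b0, b1, b2 = self.bounds
        if self.direction == "decreasing":
            if not b0 > b1 > b2:
                raise ValueError("decreasing-scale bounds must be strictly descending")
        elif self.direction == "increasing":
            if not b0 < b1 < b2:
                raise ValueError("increasing-scale bounds must be strictly ascending")
        else:
            raise ValueError("direction must be 'decreasing' or 'increasing'")

    def as_dict(self) -> dict:
        return {
            "scale": self.scale,
            "direction": self.direction,
            "bounds": list(self.bounds),
            "classes": list(self.classes),
        }


#: Healthy > 0.7; light 0.5-0.7; moderate 0.1-0.5; severe < 0.1.
LWCF_SCHEME = SeverityScheme(scale="LWCF", direction="decreasing", bounds=(0.7, 0.5, 0.1))
#: Healthy > 2.1; light 0.6-2.1; moderate 0.1-0.6; severe < 0.1.
LWCD_SCHEME = SeverityScheme(scale="LWCD", direction="decreasing", bounds=(2.1, 0.6, 0.1))
#: Healthy <= 5%; light 5-30%; moderate 30-70%; severe > 70% (fractions).
LLR_SCHEME = SeverityScheme(scale="LLR", direction="increasing", bounds=(0.05, 0.30, 0.70))


def lwc_from_weights(fw_g, dw_g):
    """LWCF and LWCD from fresh and dry sample weights (grams).

    Requires FW >= DW > 0.  Returns fractions/ratios (display as percent
    is left to the caller).
    """
    fw = np.asarray(fw_g, dtype=float)
    dw = np.asarray(dw_g, dtype=float)
    if np.any(dw <= 0):
        raise ValueError("dry weight must be positive")
    if np.any(fw < dw):
        raise ValueError("fresh weight must be at least the dry weight")
    lwcf = (fw - dw) / fw
    lwcd = (fw - dw) / dw
    if lwcf.ndim == 0:
        return float(lwcf), float(lwcd)
    return lwcf, lwcd


def llr(n_lost, n_healthy):
    """Branch leaf-loss rate: lost / (healthy + lost); returns (value, reason).

    The value is the fraction of needles lost; both counts zero yields
    NaN with a reason.  Averaging branch -> tree -> plot is a plain mean
    at each level (see :func:`larchwc.synthetic.generate_plots` for the
    5-crown-level x 4-direction sampling layout).
    """
    lost = np.asarray(n_lost, dtype=float)
    healthy = np.asarray(n_healthy, dtype=float)
    if np.any(lost < 0) or np.any(healthy < 0):
        raise ValueError("needle counts must be non-negative")
    total = lost + healthy
    bad = total == 0
    reason = "no needles counted (both counts zero)" if np.any(bad) else None
    with np.errstate(invalid="ignore"):
        out = np.where(bad, np.nan, lost / np.where(bad, 1.0, total))
    if out.ndim == 0:
        return float(out), reason
    return out, reason


def classify_severity(value, scheme: SeverityScheme):
    """Severity class code(s) (0 healthy .. 3 severe) for value(s) on a scale."""
    v = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("severity classification requires finite values")
    if np.any(v < 0):
        raise ValueError(f"negative value on the {scheme.scale} scale")
    b0, b1, b2 = scheme.bounds
    if scheme.direction == "decreasing":
        out = np.select(
            [v > b0, v >= b1, v >= b2],
            [0, 1, 2],
            default=3,
        )
    else:
        out = np.select(
            [v <= b0, v <= b1, v <= b2],
            [0, 1, 2],
            default=3,
        )
    if out.ndim == 0:
        return int(out)
    return out.astype(np.int16)


def map_damage(estimate: np.ndarray, scheme: SeverityScheme, mask: np.ndarray | None = None):
    """Classify an estimated water-content (or LLR) raster into severity.

    Returns ``(class_raster, counts)``; cells outside ``mask`` get -1.
    ``counts`` maps class name -> cell count and is conserved (sums to
    the mask size).
    """
    est = np.asarray(estimate, dtype=float)
    if mask is None:
        mask = np.ones(est.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != est.shape:
        raise ValueError("mask and estimate rasters are misaligned")
    if not mask.any():
        raise ValueError("empty mask: nothing to classify")
    if not np.all(np.isfinite(est[mask])):
        raise ValueError("estimates must be finite on the mask")
    out = np.full(est.shape, -1, dtype=np.int16)
    out[mask] = classify_severity(est[mask], scheme)
    counts = {
        name: int(np.count_nonzero(out == code))
        for code, name in enumerate(scheme.classes)
    }
    return out, counts


def confusion(predicted, reference, classes=None) -> ConfusionSummary:
    """Severity confusion matrix with OA, per-class UA/PA and kappa.

    ``classes`` defaults to the four severity codes 0..3 so the matrix
    shape is stable even when a class is absent from the data.
    """
    if classes is None:
        classes = list(range(len(SEVERITY_CLASSES)))
    pred = np.asarray(predicted).ravel()
    ref = np.asarray(reference).ravel()
    if pred.size == 0 or ref.size == 0:
        raise ValueError("empty label vectors")
    return confusion_summary(ref, pred, classes=classes)
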