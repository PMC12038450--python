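"""Synthetic Sentinel-2-like scenes of a larch forest under defoliator stress.

The generator emulates the statistical structure the analysis pipeline
assumes: a smooth latent damage field with outbreak patches, linear
spectral mixing of healthy-canopy / damaged-canopy / soil endmembers
inside the forest, four non-forest land-cover classes, the two-tier
band resolution of the sensor (10 m and 20 m), and a cohort of
10 m x 10 m field plots whose needle fresh/dry weights, water contents
and leaf-loss rates are jointly driven by the damage field.

All randomness flows from ``SceneConfig.seed``.  Each stochastic stage
draws from ``numpy.random.default_rng([seed, STAGE])`` with a fixed
per-stage integer, so stages are independently reproducible and adding
a stage never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from larchwc.geo import Affine
from larchwc.scene import (
    ALL_BANDS,
    BANDS_10M,
    BANDS_20M,
    SpectralScene,
    block_mean,
)

__all__ = [
    "SceneConfig",
    "DamageField",
    "EndmemberLibrary",
    "SceneTruth",
    "LANDCOVER_CLASSES",
    "default_endmember_library",
    "generate_damage_field",
    "generate_landcover",
    "generate_scene",
    "generate_plots",
    "tree_weights_from_water_fraction",
]

# Seed-splitting stage ids (documented scheme: rng = default_rng([seed, STAGE_*])).
_STAGE_DAMAGE = 0
_STAGE_LANDCOVER = 1
_STAGE_CANOPY = 2
_STAGE_NOISE = 3
_STAGE_PLOTS = 4

#: Land-cover legend used throughout: integer code -> class name.
LANDCOVER_CLASSES: tuple[str, ...] = ("forest", "water", "built-up", "agricultural", "bare")
FOREST = 0


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic study area.

    Defaults mirror the field campaign the pipeline was designed around:
    44 plots of 10 m x 10 m with five sample trees each, a healthy needle
    water fraction near 0.75 of fresh mass, and outbreak patches in which
    the water fraction collapses and needle loss approaches totality.
    """

    width: int = 64            # 10 m cells
    height: int = 64
    noise_sigma: float = 0.005  # additive reflectance noise, 1 sigma
    n_plots: int = 44
    trees_per_plot: int = 5
    seed: int = 0

    # Damage field
    damage_amplitude: float = 1.0   # 0 -> undamaged scene
    smoothing_length: float = 6.0   # Gaussian kernel sigma, in 10 m cells

    # Water-content coupling: w = w_healthy - w_coupling * d + noise, clipped.
    # w is the per-tree water fraction of fresh mass, i.e. exactly LWCF.
    w_healthy: float = 0.75
    w_coupling: float = 0.68
    w_noise: float = 0.02

    # Leaf-loss rate coupling: llr = llr_slope * d + llr_intercept + noise,
    # clipped to [0, 1].  Defaults line the LLR class edges up with the
    # water-content class edges implied by the water coupling above.
    llr_slope: float = 0.85
    llr_intercept: float = -0.0125
    llr_noise: float = 0.03

    # Dry needle-sample weight distribution (grams), log-normal.
    dw_log_mean: float = 1.0
    dw_log_sigma: float = 0.25

    # Landcover layout: approximate area fractions of the non-forest classes.
    nonforest_fractions: dict = field(
        default_factory=lambda: {"water": 0.06, "built-up": 0.08, "agricultural": 0.14, "bare": 0.12}
    )

    # Within-forest canopy cover (vegetation abundance) range.
    canopy_cover_min: float = 0.2
    canopy_cover_max: float = 1.0
    # Plant exact pure pixels for each endmember (pure stands / exposed soil).
    ensure_pure_pixels: bool = True

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("scene dimensions must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")


@dataclass(frozen=True)
class DamageField:
    """Latent defoliation-intensity grid, d in [0, 1] on the 10 m grid."""

    values: np.ndarray
    seed: int

    def __post_init__(self):
        v = self.values
        if not np.all(np.isfinite(v)):
            raise ValueError("damage field contains non-finite values")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("damage field values must lie in [0, 1]")


@dataclass(frozen=True)
class EndmemberLibrary:
    """Named pure-material spectra over the ten bands.

    The default library carries three endmembers — healthy larch canopy,
    damaged (defoliated) canopy, and soil — matching the three pure
    materials the unmixing stage is expected to identify.
    """

    names: tuple[str, ...]
    spectra: dict[str, np.ndarray]  # name -> (10,) reflectance in band order

    def __post_init__(self):
        for name in self.names:
            s = np.asarray(self.spectra[name], dtype=float)
            if s.shape != (len(ALL_BANDS),):
                raise ValueError(
                    f"spectrum for {name} must cover all {len(ALL_BANDS)} bands"
                )
            if s.min() < 0 or s.max() > 1:
                raise ValueError(f"spectrum for {name} must lie in [0, 1]")

    def matrix(self) -> np.ndarray:
        """(bands x k) endmember matrix in library order."""
        return np.column_stack([self.spectra[n] for n in self.names])


# Plausible reflectance shapes over (B2 B3 B4 B5 B6 B7 B8 B8A B11 B12).
# Healthy conifer canopy: strong red absorption, high NIR plateau, moderate
# SWIR.  Damaged (defoliated/desiccated) canopy: the classic red-attack
# signature — raised red, collapsed red edge and NIR, pronounced 1610 nm
# SWIR peak.  Soil: slowly increasing with wavelength.  Generator
# defaults, not site measurements.
_ENDMEMBER_SPECTRA = {
    "healthy_canopy": [0.030, 0.060, 0.035, 0.100, 0.250, 0.350, 0.400, 0.420, 0.180, 0.100],
    "damaged_canopy": [0.050, 0.070, 0.190, 0.170, 0.180, 0.190, 0.200, 0.205, 0.400, 0.240],
    "soil":           [0.080, 0.110, 0.140, 0.170, 0.190, 0.210, 0.230, 0.240, 0.300, 0.280],
}

# Spectra of the non-forest land-cover classes (same band order).
_CLASS_SPECTRA = {
    "water":        [0.060, 0.050, 0.030, 0.020, 0.012, 0.010, 0.008, 0.008, 0.004, 0.003],
    "built-up":     [0.180, 0.200, 0.220, 0.230, 0.240, 0.250, 0.260, 0.262, 0.270, 0.262],
    "agricultural": [0.050, 0.100, 0.070, 0.180, 0.300, 0.360, 0.420, 0.430, 0.250, 0.150],
    "bare":         [0.120, 0.160, 0.200, 0.240, 0.270, 0.290, 0.310, 0.320, 0.380, 0.350],
}


def default_endmember_library() -> EndmemberLibrary:
    """The three-endmember library used by the generator by default."""
    return EndmemberLibrary(
        names=("healthy_canopy", "damaged_canopy", "soil"),
        spectra={k: np.array(v) for k, v in _ENDMEMBER_SPECTRA.items()},
    )


def _smooth_field(shape, sigma, rng) -> np.ndarray:
    """Gaussian-smoothed white noise, percentile-rescaled to [0, 1]."""
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    lo, hi = np.percentile(raw, [2.0, 98.0])
    if hi - lo < 1e-12:
        return np.zeros(shape)
    return np.clip((raw - lo) / (hi - lo), 0.0, 1.0)


def generate_damage_field(config: SceneConfig) -> DamageField:
    """Smooth latent damage intensity with at least one outbreak patch.

    Gaussian-smoothed white noise is percentile-rescaled to [0, 1] (so the
    top of the distribution saturates into contiguous high-damage patches)
    and multiplied by ``damage_amplitude``.  Amplitude 0 yields an
    undamaged scene.
    """
    if config.width < 8 or config.height < 8:
        raise ValueError("scene must be at least 8x8 cells")
    rng = np.random.default_rng([config.seed, _STAGE_DAMAGE])
    base = _smooth_field((config.height, config.width), config.smoothing_length, rng)
    values = np.clip(config.damage_amplitude * base, 0.0, 1.0)
    return DamageField(values=values, seed=config.seed)


def generate_landcover(config: SceneConfig) -> np.ndarray:
    """Integer class raster (10 m): forest matrix with non-forest patches.

    A second smooth field is thresholded at the configured area quantiles,
    so each class forms contiguous patches rather than salt-and-pepper.
    """
    rng = np.random.default_rng([config.seed, _STAGE_LANDCOVER])
    u = _smooth_field((config.height, config.width), config.smoothing_length, rng)
    fr = config.nonforest_fractions
    order = ["water", "built-up", "agricultural", "bare"]
    cuts = np.cumsum([fr[c] for c in order])
    labels = np.full(u.shape, FOREST, dtype=np.int16)
    qs = np.quantile(u, cuts)
    prev = -np.inf
    for cls, q in zip(order, qs):
        sel = (u > prev) & (u <= q)
        labels[sel] = LANDCOVER_CLASSES.index(cls)
        prev = q
    return labels


@dataclass
class SceneTruth:
    """Ground truth accompanying a generated scene, for oracle testing.

    ``bands10`` is the noisy 10 m truth of all ten bands (the 20 m bands of
    the emitted scene are exact 2x2 block means of these grids).
    ``abundances`` is the (3, H, W) stack of true healthy-canopy /
    damaged-canopy / soil fractions (simplex per pixel inside the forest).
    """

    bands10: dict[str, np.ndarray]
    abundances: np.ndarray
    endmembers: EndmemberLibrary
    damage: DamageField
    landcover: np.ndarray
    forest_mask: np.ndarray


def generate_scene(
    field: DamageField,
    lib: EndmemberLibrary | None = None,
    config: SceneConfig | None = None,
) -> tuple[SpectralScene, SceneTruth]:
    """Mix endmembers into a two-resolution reflectance scene.

    Inside the forest each 10 m pixel is a linear mixture
    ``x = a_h * S_healthy + a_d * S_damaged + a_s * S_soil + noise`` where
    the canopy fraction splits healthy/damaged in proportion ``(1-d) : d``
    — i.e. the canopy spectrum interpolates healthy -> damaged with the
    local damage intensity.  Non-forest pixels take their class spectrum
    plus noise.  B2/B3/B4/B8 are emitted at 10 m; B5/B6/B7/B8A/B11/B12 at
    20 m as exact 2x2 block means of the 10 m truth, mirroring the
    sensor's native resolutions.
    """
    config = config or SceneConfig()
    lib = lib or default_endmember_library()
    for required in ("healthy_canopy", "damaged_canopy", "soil"):
        if required not in lib.spectra:
            raise ValueError(f"endmember library is missing band spectra for {required!r}")

    h, w = field.values.shape
    if h % 2 or w % 2:
        raise ValueError("scene dimensions must be even (20 m bands are 2x2 aggregates)")
    landcover = generate_landcover(config)
    if landcover.shape != (h, w):
        raise ValueError("damage field and landcover grid shapes differ")
    forest = landcover == FOREST

    rng_canopy = np.random.default_rng([config.seed, _STAGE_CANOPY])
    cover = _smooth_field((h, w), config.smoothing_length / 2.0, rng_canopy)
    cover = config.canopy_cover_min + (config.canopy_cover_max - config.canopy_cover_min) * cover

    d = field.values
    a_h = (1.0 - d) * cover
    a_d = d * cover
    a_s = 1.0 - cover
    abundances = np.stack([a_h, a_d, a_s])
    abundances[:, ~forest] = 0.0

    if config.ensure_pure_pixels and forest.sum() >= 3:
        # Pure stands exist in real outbreak mosaics; planting one exact
        # pure pixel per endmember keeps the data simplex full-rank.
        rows, cols = np.where(forest)
        rng_pp = np.random.default_rng([config.seed, _STAGE_CANOPY, 1])
        picks = rng_pp.choice(len(rows), size=3, replace=False)
        for k, p in enumerate(picks):
            abundances[:, rows[p], cols[p]] = 0.0
            abundances[k, rows[p], cols[p]] = 1.0

    E = np.column_stack(
        [lib.spectra["healthy_canopy"], lib.spectra["damaged_canopy"], lib.spectra["soil"]]
    )  # (10, 3)
    truth = np.einsum("bk,khw->bhw", E, abundances)

    for cls_name, spec in _CLASS_SPECTRA.items():
        sel = landcover == LANDCOVER_CLASSES.index(cls_name)
        truth[:, sel] = np.asarray(spec)[:, None]

    if config.noise_sigma > 0:
        rng_noise = np.random.default_rng([config.seed, _STAGE_NOISE])
        truth = truth + rng_noise.normal(0.0, config.noise_sigma, size=truth.shape)
    truth = np.clip(truth, 0.0, 1.0)

    bands10 = {name: truth[i].astype(np.float64) for i, name in enumerate(ALL_BANDS)}
    transform = Affine.from_origin(0.0, h * 10.0, 10.0, 10.0)

    bands: dict[str, np.ndarray] = {}
    gsd: dict[str, float] = {}
    for name in BANDS_10M:
        bands[name] = bands10[name].copy()
        gsd[name] = 10.0
    for name in BANDS_20M:
        bands[name] = block_mean(bands10[name], 2)
        gsd[name] = 20.0

    scene = SpectralScene(bands=bands, transform=transform, gsd=gsd)
    return scene, SceneTruth(
        bands10=bands10,
        abundances=abundances,
        endmembers=lib,
        damage=field,
        landcover=landcover,
        forest_mask=forest,
    )


def tree_weights_from_water_fraction(dw_g: float, w: float) -> float:
    """Fresh weight implied by dry weight and water fraction: FW = DW/(1-w)."""
    if not 0.0 <= w < 1.0:
        raise ValueError("water fraction must lie in [0, 1)")
    if dw_g <= 0:
        raise ValueError("dry weight must be positive")
    return dw_g / (1.0 - w)


def generate_plots(
    field: DamageField,
    config: SceneConfig | None = None,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate the field campaign: plots, trees, weighings, needle counts.

    Each plot occupies one distinct 10 m cell (optionally restricted to a
    boolean ``mask``, e.g. the forest).  For every tree a dry needle-sample
    weight ``DW`` is drawn log-normally and a water fraction
    ``w = w_healthy - w_coupling * d + noise`` (clipped to (0, 1)) sets the
    fresh weight ``FW = DW / (1 - w)``, so that per tree
    ``LWCF = (FW - DW)/FW = w`` and ``LWCD = (FW - DW)/DW = w/(1 - w)``
    hold as exact algebraic identities.  The plot leaf-loss rate is a
    noisy monotone function of damage, averaged branch -> tree -> plot
    over 5 crown levels x 4 cardinal directions per tree.

    Returns a tidy table with one row per tree
    (``plot_id, x, y, tree_id, FW_g, DW_g, LWCF, LWCD, LLR``); LLR is the
    plot-level value repeated across the plot's trees.
    """
    config = config or SceneConfig()
    h, w_cells = field.values.shape
    if mask is None:
        candidates = np.arange(h * w_cells)
    else:
        if mask.shape != field.values.shape:
            raise ValueError("mask shape must match the damage field")
        candidates = np.flatnonzero(mask.ravel())
    if config.n_plots > candidates.size:
        raise ValueError(
            f"n_plots={config.n_plots} exceeds the {candidates.size} available cells"
        )

    rng = np.random.default_rng([config.seed, _STAGE_PLOTS])
    chosen = rng.choice(candidates, size=config.n_plots, replace=False)
    rows_ = chosen // w_cells
    cols_ = chosen % w_cells

    records = []
    n_branches = 5 * 4  # five crown levels, four cardinal directions
    for pid, (r, c) in enumerate(zip(rows_, cols_), start=1):
        d = field.values[r, c]
        # Plot LLR: branch-level binomial needle counts around a mean loss
        # fraction, averaged branch -> tree -> plot.
        p_loss = float(np.clip(
            config.llr_slope * d + config.llr_intercept
            + rng.normal(0.0, config.llr_noise),
            0.0, 1.0,
        ))
        tree_llrs = []
        for _ in range(config.trees_per_plot):
            totals = rng.poisson(200, size=n_branches) + 1
            lost = rng.binomial(totals, p_loss)
            tree_llrs.append(np.mean(lost / totals))
        plot_llr = float(np.mean(tree_llrs))

        for tid in range(1, config.trees_per_plot + 1):
            dw = float(np.exp(rng.normal(config.dw_log_mean, config.dw_log_sigma)))
            w_frac = float(np.clip(
                config.w_healthy - config.w_coupling * d + rng.normal(0.0, config.w_noise),
                0.02, 0.95,
            ))
            fw = tree_weights_from_water_fraction(dw, w_frac)
            records.append({
                "plot_id": pid,
                "x": (c + 0.5) * 10.0,
                "y": (h - r - 0.5) * 10.0,
                "row": int(r),
                "col": int(c),
                "tree_id": tid,
                "FW_g": fw,
                "DW_g": dw,
                "LWCF": (fw - dw) / fw,
                "LWCD": (fw - dw) / dw,
                "LLR": plot_llr,
                "damage": float(d),
            })
    return pd.DataFrame.from_records(records)


def plot_means(trees: pd.DataFrame) -> pd.DataFrame:
    """Aggregate the per-tree table to one row per plot (mean over trees)."""
    return (
        trees.groupby("plot_id")
        .agg(
            x=("x", "first"), y=("y", "first"),
            row=("row", "first"), col=("col", "first"),
            LWCF=("LWCF", "mean"), LWCD=("LWCD", "mean"),
            LLR=("LLR", "first"), damage=("damage", "first"),
        )
        .reset_index()
    )
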