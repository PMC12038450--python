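"""End-to-end orchestration of the water-content analysis.

Stage order follows the method's technical roadmap: simulate (or load)
a scene -> sharpen to 10 m -> land-cover classification and forest
extraction -> spectral unmixing -> vegetation-index features ->
sensitive-index selection -> SVR/BP regression under LOOCV -> severity
mapping -> LLR cross-validation.  A single integer seed makes the whole
run reproducible; the effective configuration is written next to the
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from larchwc import damage as dmg
from larchwc import landcover as lc
from larchwc import raster_io, synthetic, unmixing, vegindex
from larchwc.features import SelectionResult, correlation_screen, rfecv
from larchwc.regression import (
    BPConfig,
    SVRConfig,
    fit_predict_bp,
    fit_predict_svr,
    loocv,
)
from larchwc.scene import BAND_WAVELENGTHS_NM
from larchwc.sharpening import SharpenConfig, sharpen_scene
from larchwc.synthetic import SceneConfig

__all__ = ["PipelineConfig", "RunReport", "run"]

_STAGE_TRAINING = 10  # seed-splitting id for land-cover training samples

STAGES = (
    "simulate", "sharpen", "landcover", "unmix", "indices",
    "select", "fit", "map", "validate",
)


@dataclass
class PipelineConfig:
    """Everything one run needs; serializable to JSON."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    sharpen: SharpenConfig = field(default_factory=SharpenConfig)
    svr: SVRConfig = field(default_factory=SVRConfig)
    bp: BPConfig = field(default_factory=BPConfig)
    use_screen: bool = True
    screen_threshold: float = 0.4
    use_rfecv: bool = True
    rfecv_folds: int = 5
    landcover_train_per_class: int = 60
    min_vegetation_abundance: float = 0.5
    targets: tuple[str, ...] = ("LWCF", "LWCD")
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        # One master seed drives every stage.
        if self.scene.seed != self.seed:
            self.scene = dataclasses.replace(self.scene, seed=self.seed)
        if self.bp.seed != self.seed:
            self.bp = dataclasses.replace(self.bp, seed=self.seed)

    def as_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            return obj

        return enc(self)


@dataclass
class RunReport:
    """Artifacts and metrics of one pipeline run."""

    config: PipelineConfig
    metrics: dict
    paths: dict
    timings: dict
    seed: int

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config.as_dict(),
            "metrics": self.metrics,
            "paths": {k: str(v) for k, v in self.paths.items()},
            "timings_s": self.timings,
        }


def _train_samples(scene10, class_raster, per_class, seed):
    """Sample labelled training spectra per class (operator's polygons)."""
    rng = np.random.default_rng([seed, _STAGE_TRAINING])
    stack = scene10.stack()
    X = stack.reshape(stack.shape[0], -1).T
    y = np.asarray(class_raster).ravel()
    Xs, ys = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        take = min(per_class, idx.size)
        pick = rng.choice(idx, size=take, replace=False)
        Xs.append(X[pick])
        ys.append(np.full(take, c))
    return np.vstack(Xs), np.concatenate(ys)


def run(config: PipelineConfig | None = None) -> RunReport:
    """Execute all stages in roadmap order on a synthetic scene."""
    config = config or PipelineConfig()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    metrics: dict = {}
    paths: dict = {}
    timings: dict = {}

    def _stage(name):
        timings[name] = time.perf_counter()

    def _done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    # --- simulate -----------------------------------------------------
    _stage("simulate")
    try:
        field_ = synthetic.generate_damage_field(config.scene)
        scene, truth = synthetic.generate_scene(field_, config=config.scene)
        trees = synthetic.generate_plots(field_, config.scene, mask=truth.forest_mask)
        plots = synthetic.plot_means(trees)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    if outdir:
        paths["scene"] = raster_io.write_scene(scene, outdir / "scene")
        paths["plots"] = raster_io.write_plot_table(trees, outdir / "plots.csv")
    metrics["simulate"] = {
        "n_plots": int(plots.shape[0]),
        "n_trees": int(trees.shape[0]),
        "forest_fraction_true": float(truth.forest_mask.mean()),
    }
    _done("simulate")

    # --- sharpen ------------------------------------------------------
    _stage("sharpen")
    scene10 = sharpen_scene(scene, config.sharpen)
    _done("sharpen")

    # --- landcover ----------------------------------------------------
    _stage("landcover")
    Xtr, ytr = _train_samples(
        scene10, truth.landcover, config.landcover_train_per_class, config.seed
    )
    model = lc.fit_mlc(Xtr, ytr)
    labels = lc.classify_mlc(model, scene10)
    acc = lc.map_accuracy(labels, truth.landcover)
    fmask = lc.forest_mask(labels, forest_label=synthetic.FOREST)
    metrics["landcover"] = {
        "oa": acc.oa, "kappa": acc.kappa,
        "n_forest_points": int(fmask.sum()),
    }
    if outdir:
        paths["landcover"] = raster_io.write_raster(
            outdir / "landcover.tif", labels.astype(np.float32), scene10.transform,
            band_names=["class"], meta={"classes": list(synthetic.LANDCOVER_CLASSES)},
        )
    _done("landcover")

    # --- unmix --------------------------------------------------------
    _stage("unmix")
    stack = scene10.stack()
    X_forest = stack[:, fmask]
    noise, _ = unmixing.estimate_noise(X_forest)
    k_hat, _basis = unmixing.hysime(X_forest, noise)
    k_use = max(k_hat, 1)
    ems = unmixing.vca(X_forest, k_use, seed=config.seed)
    A = unmixing.fcls(X_forest, ems.spectra)

    E_true = truth.endmembers.matrix()
    veg_abund = np.zeros(fmask.shape)
    ab_rmse = float("nan")
    if k_use == E_true.shape[1]:
        perm = unmixing.align_endmembers(ems.spectra, E_true)
        A_aligned = A[perm]
        both = fmask & truth.forest_mask
        sel = both[fmask]  # positions within the forest pixel set
        ab_rmse = float(np.sqrt(np.mean(
            (A_aligned[:, sel] - truth.abundances[:, both]) ** 2
        )))
        veg_abund[fmask] = A_aligned[0] + A_aligned[1]  # healthy + damaged canopy
    else:
        veg_abund[fmask] = 1.0  # cannot split materials; no filtering
    metrics["unmix"] = {
        "hysime_k": int(k_hat),
        "abundance_rmse": ab_rmse,
        "n_pixels": int(X_forest.shape[1]),
    }
    if outdir:
        em_df = pd.DataFrame(
            ems.spectra,
            index=scene10.band_names,
            columns=[f"endmember_{i+1}" for i in range(k_use)],
        )
        em_df.insert(0, "wavelength_nm",
                     [BAND_WAVELENGTHS_NM[b] for b in scene10.band_names])
        em_df.to_csv(outdir / "endmembers.csv", index_label="band")
        paths["endmembers"] = outdir / "endmembers.csv"
        amap = np.zeros((k_use,) + fmask.shape, dtype=np.float32)
        amap[:, fmask] = A
        paths["abundance"] = raster_io.write_raster(
            outdir / "abundance.tif", amap, scene10.transform,
            band_names=[f"endmember_{i+1}" for i in range(k_use)],
        )
    _done("unmix")

    # --- indices ------------------------------------------------------
    _stage("indices")
    ft = vegindex.compute_feature_table(scene10, plots=plots)
    table = ft.data.join(plots.set_index("plot_id")[["LWCF", "LWCD", "LLR"]])
    if outdir:
        table.to_csv(outdir / "features.csv")
        paths["features"] = outdir / "features.csv"
    metrics["indices"] = {
        "n_indices": len(ft.feature_names),
        "n_missing_values": int(ft.data.isna().sum().sum()),
    }
    _done("indices")

    # --- select -------------------------------------------------------
    _stage("select")
    selections: dict[str, SelectionResult | None] = {}
    selected_features: dict[str, list[str]] = {}
    for target in config.targets:
        sub = table[ft.feature_names + [target]].dropna()
        feats = list(ft.feature_names)
        if config.use_screen:
            feats = correlation_screen(sub[feats + [target]], target,
                                       threshold=config.screen_threshold)
        if config.use_rfecv:
            res = rfecv(sub[feats + [target]], target,
                        folds=config.rfecv_folds, seed=config.seed)
            selections[target] = res
            selected_features[target] = res.selected
        else:
            selections[target] = None
            selected_features[target] = feats
    metrics["select"] = {
        t: {"n_selected": len(selected_features[t]), "selected": selected_features[t]}
        for t in config.targets
    }
    if outdir:
        with open(outdir / "selection.json", "w") as fh:
            json.dump(
                {t: (selections[t].as_dict() if selections[t] else
                     {"selected": selected_features[t]}) for t in config.targets},
                fh, indent=2,
            )
        paths["selection"] = outdir / "selection.json"
    _done("select")

    # --- fit ----------------------------------------------------------
    _stage("fit")
    fit_metrics: dict = {}
    loocv_preds: dict = {}
    for target in config.targets:
        cols = selected_features[target] + [target]
        sub = table[cols].dropna()
        ev_svr = loocv(sub, target, fit_predict_svr, config.svr)
        ev_bp = loocv(sub, target, fit_predict_bp, config.bp)
        fit_metrics[target] = {"svr": ev_svr.as_dict(), "bp": ev_bp.as_dict()}
        loocv_preds[target] = (sub.index.to_numpy(), ev_svr.y, ev_svr.y_hat)
    metrics["fit"] = fit_metrics
    if outdir:
        rows = []
        for target, (ids, y, y_hat) in loocv_preds.items():
            for pid, yy, pp in zip(ids, y, y_hat):
                rows.append({"target": target, "plot_id": int(pid),
                             "observed": yy, "predicted": pp})
        pd.DataFrame(rows).to_csv(outdir / "loocv_predictions.csv", index=False)
        paths["loocv_predictions"] = outdir / "loocv_predictions.csv"
    _done("fit")

    # --- map ----------------------------------------------------------
    _stage("map")
    px = vegindex.compute_feature_table(
        scene10, mask=fmask,
        abundance=veg_abund, min_abundance=config.min_vegetation_abundance,
    )
    rows_px, cols_px = np.where(fmask)
    map_metrics: dict = {}
    for target in config.targets:
        scheme = dmg.LWCF_SCHEME if target == "LWCF" else dmg.LWCD_SCHEME
        cols = selected_features[target]
        sub = table[cols + [target]].dropna()
        pxsub = px.data[cols].dropna()
        est = np.full(fmask.shape, np.nan)
        if len(pxsub):
            preds = fit_predict_svr(
                sub[cols].to_numpy(), sub[target].to_numpy(),
                pxsub.to_numpy(), config.svr,
            )
            # water content cannot be negative on either scale
            preds = np.clip(preds, 0.0, None)
            keep = pxsub.index.to_numpy()
            est[rows_px[keep], cols_px[keep]] = preds
        valid = np.isfinite(est)
        class_raster, counts = dmg.map_damage(est, scheme, mask=valid)
        map_metrics[target] = {"class_counts": counts, "n_mapped": int(valid.sum())}
        if outdir:
            paths[f"damage_{target}"] = raster_io.write_raster(
                outdir / f"damage_{target}.tif",
                class_raster.astype(np.float32), scene10.transform,
                band_names=["severity"],
                meta={"classes": list(dmg.SEVERITY_CLASSES)},
            )
    metrics["map"] = map_metrics
    _done("map")

    # --- validate -----------------------------------------------------
    _stage("validate")
    validate_metrics: dict = {}
    for target in config.targets:
        scheme = dmg.LWCF_SCHEME if target == "LWCF" else dmg.LWCD_SCHEME
        ids, y, y_hat = loocv_preds[target]
        llr_by_plot = plots.set_index("plot_id").loc[ids, "LLR"].to_numpy()
        ref = dmg.classify_severity(llr_by_plot, dmg.LLR_SCHEME)
        pred = dmg.classify_severity(np.clip(y_hat, 0.0, None), scheme)
        cs = dmg.confusion(pred, ref)
        validate_metrics[target] = cs.as_dict()
    metrics["validate"] = validate_metrics
    _done("validate")

    report = RunReport(
        config=config, metrics=metrics, paths=paths, timings=timings, seed=config.seed
    )
    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report.as_dict(), fh, indent=2, default=float)
        paths["report"] = outdir / "report.json"
    return report
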