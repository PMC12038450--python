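# larchwc

Estimation of larch needle water content under defoliator stress from
Sentinel-2-like multispectral imagery.

Outbreaks of the larch looper (*Erannis jacobsoni* Djak.) defoliate
boreal larch forests over large areas, and the water content of the
remaining needles responds early and strongly to the stress.  Field
crews measure it by weighing needle samples fresh (FW) and after
drying (DW):

```
LWCF = (FW − DW) / FW        fresh-weight water content, in [0, 1)
LWCD = (FW − DW) / DW        dry-weight water content,  ≥ 0
```

linked by LWCD = LWCF/(1 − LWCF).  `larchwc` implements a complete,
tested pipeline that scales these plot measurements to whole scenes:

1. **Sharpening** — 20 m red-edge/SWIR bands to the 10 m grid by local
   linear regression with an exact 2×2 block-consistency constraint.
2. **Land cover** — Gaussian maximum-likelihood classification
   (forest / water / built-up / agricultural / bare) and forest-mask
   extraction, scored by OA and kappa.
3. **Spectral unmixing** — HySime noise/subspace estimation, VCA
   endmember extraction and FCLS abundance inversion
   (x = Ea + ε, a ≥ 0, Σa = 1) on the forest pixels.
4. **Vegetation indices** — a registry of 40 index formulas over the
   ten bands (NDVI, NDMI, AFRI1600, SIreg, SCCI, …).
5. **Sensitive-index selection** — Pearson screening (|r| > 0.4) and
   recursive feature elimination with cross-validation (RFECV).
6. **Regression** — RBF-kernel SVR (C = 10, γ = 0.1) and a 40-node
   back-propagation network, evaluated by leave-one-out
   cross-validation with MAE and RMSE.
7. **Damage mapping** — four-level severity classification (healthy /
   light / moderate / severe) of the mapped water content, validated
   against leaf-loss-rate (LLR) classes via confusion matrices.

Because the field campaigns such methods are built on are rarely
public, the package includes a first-class synthetic-scene generator:
a latent damage field with outbreak patches drives linear spectral
mixing of healthy-canopy / damaged-canopy / soil endmembers, the
two-tier 10 m / 20 m band layout, and a 44-plot, 5-trees-per-plot
field campaign whose LWCF, LWCD and LLR are jointly coupled to the
damage field.  Every stage is therefore testable end to end against
known ground truth.  See `docs/methods.md` for the full model
description and its limitations.

## Worked example

```python
from larchwc.pipeline import PipelineConfig, run
from larchwc.synthetic import SceneConfig

report = run(PipelineConfig(scene=SceneConfig(seed=42), seed=42,
                            outdir="scratch/demo_run"))
```

(`examples/06_full_pipeline.py`; the `examples/` directory has one
short script per capability.)  Output:

```
stages: simulate, sharpen, landcover, unmix, indices, select, fit, map, validate
land cover OA 1.000
HySime k = 3
LWCF: 13 sensitive indices, SVR LOOCV MAE 0.0523 / RMSE 0.0665, severity agreement with LLR: OA 86.36%, kappa 0.672
LWCD: 10 sensitive indices, SVR LOOCV MAE 0.1699 / RMSE 0.2812, severity agreement with LLR: OA 54.55%, kappa 0.274
```

Reading the numbers: the classifier separates the five synthetic land
covers essentially perfectly; HySime finds the three pure materials
mixed into the forest pixels; RFECV keeps 13 of 40 indices for
fresh-weight and 10 for dry-weight water content; SVR predicts
held-out plot LWCF to an MAE of ≈ 0.05 on the 0–1 fraction scale
(LWCD errors are larger because that scale is unbounded); and the
severity classes inferred from mapped water content agree with the
independent leaf-loss-rate classes well beyond chance (kappa > 0).
Rerunning with the same seed reproduces every number; the run
directory contains the scene GeoTIFFs, plot/feature CSVs, abundance
and severity rasters and a JSON report.

A thin CLI mirrors the stages:

```
larchwc run-all --out scratch/demo_run --seed 42
larchwc simulate --out scratch/scene --seed 1
larchwc sharpen --in scratch/scene --out scratch/scene10
larchwc registry
```

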