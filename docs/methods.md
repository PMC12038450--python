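# Methods

`larchwc` implements a complete analysis chain for estimating larch
needle water content under defoliator (larch looper) stress from
Sentinel-2-like multispectral reflectance, and for mapping stand-level
damage severity from the estimates.  Because suitable field campaigns
are rarely public, the package ships a synthetic-scene generator that
reproduces the statistical structure the chain assumes, so every stage
is testable end to end.

## Water-content quantities

From a fresh/dry weighing of a needle sample (FW, DW in grams):

- **LWCF** = (FW − DW)/FW — water as a fraction of fresh mass, in [0, 1).
- **LWCD** = (FW − DW)/DW — water relative to dry mass, unbounded above.
- Identity: LWCD = LWCF/(1 − LWCF); enforced to 1e-12 on all generated
  records.

The **leaf loss rate** LLR = N_lost/(N_healthy + N_lost) is the field
severity indicator, averaged branch → tree → plot, with branches
sampled over five crown levels × four cardinal directions.

All three scales are stored as raw fractions/ratios; "×100 %" is
treated purely as display formatting, because the severity thresholds
(0.7, 2.1, …) are stated on the fractional scale.

### Severity schemes

Four classes per scale.  The published intervals share endpoints, so
closures were fixed to make the classes exhaustive and disjoint:

- LWCF: severe < 0.1 ≤ moderate < 0.5 ≤ light ≤ 0.7 < healthy
- LWCD: severe < 0.1 ≤ moderate < 0.6 ≤ light ≤ 2.1 < healthy
- LLR: healthy ≤ 0.05 < light ≤ 0.30 < moderate ≤ 0.70 < severe

The LWCF 0.7 and LWCD 2.1 healthy thresholds are mutually inconsistent
under the LWCD identity (0.7 ↔ 2.333); both are kept as published,
applied independently per scale.  In the LLR formula the loss count is
the numerator, so that LLR measures loss (consistent with "healthy"
meaning at most 5 % loss).

## Synthetic scenes

The generator emulates, on a 10 m grid (default 64×64 cells):

- **Latent damage field** d ∈ [0, 1]: Gaussian-smoothed white noise
  (smoothing length 6 cells), percentile-rescaled so the upper tail
  saturates into contiguous outbreak patches; multiplied by an
  amplitude (0 ⇒ undamaged scene).
- **Land cover**: a second smooth field thresholded at area quantiles
  — forest matrix (~60 %) with water/built-up/agricultural/bare
  patches, each with a fixed class spectrum.
- **Linear mixing** inside the forest: per pixel
  x = a_h·S_healthy + a_d·S_damaged + a_s·S_soil + ε, with canopy cover
  from a third smooth field (0.2–1.0) split healthy : damaged as
  (1 − d) : d, and ε ~ N(0, σ²) i.i.d. per band (default σ = 0.005
  reflectance).  One exact pure pixel per endmember is planted inside
  the forest (pure stands and exposed soil exist in real outbreak
  mosaics); this keeps the data simplex full-rank for geometric
  endmember extraction.
- **Two-tier resolution**: B2/B3/B4/B8 are emitted at 10 m, the
  red-edge/narrow-NIR/SWIR sextet at 20 m as exact 2×2 block means of
  the 10 m truth, mirroring the sensor layout.
- **Field campaign**: 44 plots of one 10 m cell each, 5 trees per plot.
  Per tree, DW ~ logN(1, 0.25²) grams and water fraction
  w = 0.75 − 0.68·d + N(0, 0.02²), clipped to (0.02, 0.95);
  FW = DW/(1 − w), so the per-tree LWCF equals w exactly.  Plot LLR
  uses branch-level binomial needle counts around a mean loss
  p = 0.85·d − 0.0125 + N(0, 0.03²), clipped to [0, 1].  The two
  couplings are aligned so the water-content and leaf-loss severity
  class edges refer to comparable damage levels; the quantitative
  coupling is a free generator parameter (no published value exists)
  and is fixed here once.

Default endmember spectra are plausible shapes, not site measurements:
healthy conifer canopy (strong red absorption, high NIR plateau),
damaged canopy (the red-attack signature: raised red, collapsed red
edge and NIR, pronounced 1610 nm SWIR peak), and soil (slowly
increasing with wavelength).

All randomness flows from one integer seed: each stage draws from
`numpy.random.default_rng([seed, STAGE])` with a fixed stage id, so
stages are independently reproducible.

**What the generator does not emulate**: radiative transfer
(PROSAIL-class realism), atmospheric and topographic effects, spatially
correlated or signal-dependent sensor noise, sub-pixel plot/grid
misregistration, and phenological variation.  Passing tests therefore
demonstrate the correctness and internal consistency of the chain
under its stated model — linear mixing, Gaussian noise, monotone
damage–water coupling — not field accuracy on real imagery.

## Sharpening

The 20 m bands are brought to 10 m by local linear regression: per
low-resolution window (default 15 of the 10 m cells, i.e. a 7×7
low-resolution neighbourhood), the 20 m band is regressed on
block-averaged 10 m bands with a small ridge (1e-3) on the slopes, the
fit is applied at 10 m, and the block residual is added back so every
2×2 block mean of the output equals the input exactly (enforced to
1e-9).  This is a deliberate stand-in for heavier multi-band
super-resolution tools: only the objective (consistency between the
downsampled reconstruction and the observation) is reproduced, as an
explicit, testable contract.

## Land cover

ENVI-style Gaussian maximum likelihood: per class, sample mean and
covariance with a ridge of 1e-6 × the mean band variance (synthetic
classes can be degenerate), priors proportional to class counts (flag
for equal priors).  Pixels are assigned by the quadratic discriminant
g_c(x) = ln π_c − ½ln|Σ_c| − ½(x−μ_c)ᵀΣ_c⁻¹(x−μ_c), ties to the first
class.  Accuracy is scored against the generator's true class raster
(no external land-use product exists for synthetic scenes) with
OA/UA/PA and kappa.

## Spectral unmixing

The chain follows the original published formulations:

- **Noise estimation**: each band regressed on the other nine; the
  residuals are the noise estimate.
- **HySime**: eigendecompose the estimated signal correlation
  R̂_s = (X−ξ̂)(X−ξ̂)ᵀ/n; include an eigendirection when its projected
  signal power exceeds twice its projected noise power (the
  minimum-MSE rule).  Pure noise floors at k ≤ 1.
- **VCA**: project to a k-dimensional subspace — projective projection
  above the SNR threshold 15 + 10·log₁₀k dB, mean-removed PCA plus a
  constant component below it — then iteratively take the pixel with
  the largest |projection| on a direction orthogonal to the span of
  the endmembers found so far.  Deterministic given a seed.
- **FCLS**: non-negative least squares on the sum-to-one-augmented
  system with augmentation weight δ = 1/(20·max|E|), followed by an
  exact renormalization onto the simplex.  The augmentation bias is
  orders of magnitude below the resolution of a 0.01-step simplex grid
  search, which the tests use as the independent oracle.

Endmember sets are aligned to references for scoring by Hungarian
assignment on the pairwise spectral-angle matrix.  Downstream feature
extraction can filter pixels by vegetation abundance (default
threshold 0.5) when the estimated endmember count matches the library.

## Vegetation indices

A 40-entry registry with the formula string as printed in the source
table, a machine expression, and a provenance flag.  Lost superscripts
("B82", "B80.5") are read as powers; five garbled entries (CTVI, MNLI,
MTVI2, AFRI1600, AFRI2100) evaluate canonical literature forms with
the printed string retained; SIWSI's printed expression lost its
parentheses and is evaluated in its canonical normalized-difference
form.  SCCI is evaluated exactly as printed (100·(B8−B4)/NDVI, which
reduces to 100·(B8+B4)), and the OSAVI/OSAVIreg band choice is kept as
printed though plausibly swapped — all such readings are recorded in
the entry notes.  Undefined values (zero denominator, negative
radicand) surface as NaN plus an explicit reason; no NaN is silent.

## Feature selection

Pearson screen (keep |r| > 0.4 against the target; pass-through with a
warning if nothing survives) followed by RFECV: at each step a linear
SVR on standardized features ranks the remaining features by |w|, the
subset is scored by 5-fold shuffled CV (negative RMSE), and the
weakest feature is dropped, one per step; the CV-optimal subset size
wins, ties to the smaller subset.  Linear-weight ranking is used
because the RBF-kernel estimator exposes no native importances; the
final predictive models are fit separately.  The index sets selected
on the original field campaign (3 for LWCF, 10 for LWCD) ship as
reference configuration.

## Regression and evaluation

- **SVR**: RBF kernel, C = 10, γ = 0.1, ε = 0.1 (ε unstated in the
  protocol; config-exposed), features z-scored per training fold.
- **BP network**: one hidden layer of 40 logistic units, linear
  output, plain (momentum-free) SGD at constant rate 0.01, ≤ 1000
  epochs, early stop after 50 epochs without training-loss improvement
  (no validation split — the 44-plot cohort is too small under
  LOOCV).  The target is min-max scaled for training and
  inverse-transformed.
- **LOOCV**: n fits, each predicting one held-out plot; MAE and RMSE
  over the n held-out predictions.  MAE ≤ RMSE is asserted on every
  evaluation.

The published hyperparameters are treated as final; no re-tuning.

## Pipeline

`larchwc.pipeline.run` chains simulate → sharpen → landcover → unmix →
indices → select → fit → map → validate, with one master seed and the
effective configuration serialized next to the outputs.  Default
problem sizes — a 64×64-cell scene, 44 plots, 100-seed/20-seed
simulation studies in the acceptance suite — were chosen to exercise
every stage at full fidelity while keeping a complete run in tens of
seconds.  Mapped water-content estimates are clipped below at 0 before
severity classification (negative water content is physically
impossible, and the severity schemes reject negative values).

## Known limitations

- The sharpener is not a reimplementation of any specific
  super-resolution product; only the consistency objective is shared.
- VCA requires (near-)pure pixels; on scenes without them the
  recovered endmembers are the most extreme mixtures, and abundance
  errors scale with the simplex shrinkage.
- The SVR-vs-BP accuracy ordering observed on the original field data
  is seed-dependent on synthetic cohorts and is logged, not asserted.
- Severity boundary closures at shared endpoints are a package
  decision (documented above); analyses sensitive to boundary cases
  should use the scheme objects explicitly.
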