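"""The 40-entry vegetation-index registry and per-plot features.

Prints a few registry entries (including how garbled printed formulas
were handled), evaluates indices on a single spectrum, and builds the
plot-level feature table used for regression.
"""

from larchwc.sharpening import sharpen_scene
from larchwc.synthetic import (
    SceneConfig,
    generate_damage_field,
    generate_plots,
    generate_scene,
    plot_means,
)
from larchwc.vegindex import compute_feature_table, compute_index, registry

print(f"registered indices: {len(registry())}")
for d in registry():
    if d.provenance == "canonical_substituted":
        print(f"  {d.name:10s} printed {d.printed_formula!r} -> {d.canonical_formula}")

bands = {"B2": 0.03, "B3": 0.06, "B4": 0.04, "B5": 0.10, "B6": 0.25,
         "B8": 0.40, "B8A": 0.42, "B11": 0.18, "B12": 0.10}
for name in ("NDVI", "NDMI", "SIreg", "AFRI1600", "SCCI"):
    print(f"{name}: {compute_index(name, bands):.4f}")

cfg = SceneConfig(seed=42)
field = generate_damage_field(cfg)
scene, truth = generate_scene(field, config=cfg)
plots = plot_means(generate_plots(field, cfg, mask=truth.forest_mask))
ft = compute_feature_table(sharpen_scene(scene), plots=plots[["plot_id", "row", "col"]])
print(f"feature table: {ft.data.shape[0]} plots x {len(ft.feature_names)} indices, "
      f"{int(ft.data.isna().sum().sum())} missing values")

# A healthy-canopy spectrum yields high NDVI/NDMI; the feature table is
# the 44-plot x 40-index input to sensitive-index selection.
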