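"""Vegetation-index registry: structure, hand-computed values, fuzzing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from larchwc.geo import Affine
from larchwc.scene import SpectralScene
from larchwc.vegindex import (
    compute_feature_table,
    compute_index,
    evaluate_index,
    registry,
    registry_names,
)

ALL_SYMBOLS = ("B2", "B3", "B4", "B5", "B6", "B8", "B8A", "B11", "B12")

#: Indices implemented in explicit normalized-difference form.
ND_INDICES = ("GNDVI", "NDGI", "NDI45", "NDII", "NDMI", "NDVI", "NDREI",
              "NDVIreg", "SIWSI", "red_edge_ndvi", "RDVIreg")

positive_bands = st.fixed_dictionaries(
    {b: st.floats(1e-3, 1.0, allow_nan=False) for b in ALL_SYMBOLS}
)


class TestRegistryStructure:
    def test_forty_entries_with_unique_names(self):
        names = registry_names()
        assert len(names) == 40
        assert len(set(names)) == 40

    def test_red_edge_duplicates_evaluate_identically(self):
        bands = {"B8": 0.41, "B5": 0.17}
        vals = {n: compute_index(n, bands) for n in ("NDVIreg", "RDVIreg", "red_edge_ndvi")}
        assert len(set(round(v, 15) for v in vals.values())) == 1

    def test_every_entry_declares_provenance(self):
        for d in registry():
            assert d.provenance in ("as_printed", "canonical_substituted")
            if d.provenance == "canonical_substituted":
                assert d.canonical_formula  # both forms carried


class TestHandComputedValues:
    @pytest.mark.parametrize(
        "name, bands, expected",
        [
            ("NDVI", {"B8": 0.5, "B4": 0.1}, 0.666667),
            ("NDVI", {"B8": 0.3, "B4": 0.3}, 0.0),
            ("DSWI-4", {"B3": 0.2, "B4": 0.1}, 2.0),
            ("GDVI", {"B8": 0.4, "B3": 0.15}, 0.25),
            ("SIreg", {"B2": 0.05, "B5": 0.15}, 0.2),
            ("CCRI", {"B4": 0.1, "B5": 0.2}, 0.5),
            ("PSSR", {"B8": 0.4, "B4": 0.1}, 4.0),
            ("VGCI", {"B8": 0.4, "B4": 0.1}, 3.0),
            ("Int2", {"B3": 0.1, "B4": 0.2, "B5": 0.3}, 0.3),
            ("SI1", {"B5": 0.2, "B4": 0.1}, 0.02),
            ("CIreg", {"B8": 0.4, "B5": 0.2}, 1.0),
            # SCCI as printed: 100*(B8-B4)/NDVI = 100*(B8+B4)
            ("SCCI", {"B8": 0.5, "B4": 0.1}, 60.0),
            ("SAVI", {"B8": 0.4, "B4": 0.1}, 1.5 * 0.3 / 1.0),
            ("EVI2", {"B8": 0.4, "B4": 0.1}, 2.5 * 0.3 / (0.4 + 0.24 + 1)),
            ("NLI", {"B8": 0.5, "B4": 0.1}, (0.25 - 0.1) / (0.25 + 0.1)),
            ("AFRI1600", {"B8": 0.4, "B11": 0.2},
             (0.4 - 0.66 * 0.2) / (0.4 + 0.66 * 0.2)),
        ],
    )
    def test_value(self, name, bands, expected):
        assert compute_index(name, bands) == pytest.approx(expected, abs=1e-6)

    def test_unknown_index_raises(self):
        with pytest.raises(KeyError, match="unknown"):
            compute_index("NOPE", {"B8": 0.5})

    def test_missing_band_is_named(self):
        with pytest.raises(KeyError, match="B4"):
            compute_index("NDVI", {"B8": 0.5})

    def test_division_by_zero_is_flagged(self):
        value, reason = evaluate_index("NDVI", {"B8": 0.0, "B4": 0.0})
        assert np.isnan(value) and "zero" in reason
        # SCCI undefined where NDVI = 0
        value, reason = evaluate_index("SCCI", {"B8": 0.2, "B4": 0.2})
        assert np.isnan(value) and reason is not None


class TestRegistryProperties:
    @settings(max_examples=60, deadline=None)
    @given(bands=positive_bands)
    def test_normalized_difference_indices_bounded(self, bands):
        for name in ND_INDICES:
            v = compute_index(name, bands)
            assert -1.0 <= v <= 1.0

    @settings(max_examples=40, deadline=None)
    @given(bands=positive_bands)
    def test_every_entry_finite_or_flagged(self, bands):
        for d in registry():
            value, reason = evaluate_index(d.name, bands)
            assert np.isfinite(value) or reason is not None


class TestFeatureTable:
    def _scene(self, n=4):
        rng = np.random.default_rng(0)
        bands = {
            b: rng.uniform(0.05, 0.6, (n, n))
            for b in ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12")
        }
        return SpectralScene(
            bands=bands, transform=Affine.from_origin(0, n * 10.0, 10, 10),
            gsd={b: 10.0 for b in bands},
        )

    def test_single_cell_plot_equals_direct_index(self):
        scene = self._scene()
        plots = pd.DataFrame({"plot_id": [1], "row": [2], "col": [1]})
        ft = compute_feature_table(scene, plots=plots)
        cell = {b: scene.bands[b][2, 1] for b in scene.band_names}
        assert ft.data.loc[1, "NDVI"] == pytest.approx(compute_index("NDVI", cell))
        assert ft.data.loc[1, "SIreg"] == pytest.approx(compute_index("SIreg", cell))

    def test_two_cell_plot_is_mean_of_cells(self):
        scene = self._scene()
        plots = pd.DataFrame({"plot_id": [1, 1], "row": [0, 1], "col": [0, 0]})
        ft = compute_feature_table(scene, plots=plots)
        v0 = compute_index("NDVI", {b: scene.bands[b][0, 0] for b in scene.band_names})
        v1 = compute_index("NDVI", {b: scene.bands[b][1, 0] for b in scene.band_names})
        assert ft.data.loc[1, "NDVI"] == pytest.approx((v0 + v1) / 2)

    def test_abundance_filter_flags_fully_filtered_plot(self):
        scene = self._scene()
        plots = pd.DataFrame({"plot_id": [1, 2], "row": [0, 1], "col": [0, 1]})
        ab = np.zeros((4, 4))
        ab[1, 1] = 0.9  # only plot 2's cell is vegetated enough
        ft = compute_feature_table(scene, plots=plots, abundance=ab, min_abundance=0.5)
        assert np.isnan(ft.data.loc[1, "NDVI"])
        assert "abundance" in ft.flags.loc[1, "NDVI"]
        assert np.isfinite(ft.data.loc[2, "NDVI"])

    def test_point_outside_scene_is_flagged(self):
        scene = self._scene()
        plots = pd.DataFrame({"plot_id": [9], "row": [99], "col": [0]})
        ft = compute_feature_table(scene, plots=plots)
        assert np.isnan(ft.data.loc[9, "NDVI"])
        assert "outside" in ft.flags.loc[9, "NDVI"]

    def test_mixed_resolution_scene_rejected(self, default_scene):
        with pytest.raises(ValueError, match="10 m"):
            compute_feature_table(default_scene, mask=np.ones((2, 2), bool))
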