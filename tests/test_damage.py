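"""Field formulas, severity schemes and confusion analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from larchwc.damage import (
    LLR_SCHEME,
    LWCD_SCHEME,
    LWCF_SCHEME,
    SEVERITY_CLASSES,
    classify_severity,
    confusion,
    llr,
    lwc_from_weights,
    map_damage,
)


class TestWeights:
    def test_hand_arithmetic(self):
        lwcf, lwcd = lwc_from_weights(10.0, 3.0)
        assert lwcf == pytest.approx(0.7)
        assert lwcd == pytest.approx(7.0 / 3.0)

    def test_equal_weights_give_zero(self):
        assert lwc_from_weights(5.0, 5.0) == (0.0, 0.0)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="dry"):
            lwc_from_weights(5.0, 0.0)
        with pytest.raises(ValueError, match="fresh"):
            lwc_from_weights(2.0, 3.0)

    @settings(max_examples=100, deadline=None)
    @given(
        dw=st.floats(1e-3, 100, allow_nan=False),
        water=st.floats(0, 50, allow_nan=False),
    )
    def test_fraction_ratio_identity(self, dw, water):
        fw = dw + water
        lwcf, lwcd = lwc_from_weights(fw, dw)
        if lwcf < 1:
            assert lwcd == pytest.approx(lwcf / (1 - lwcf), abs=1e-9, rel=1e-9)


class TestLLR:
    def test_values(self):
        assert llr(50, 50)[0] == pytest.approx(0.5)
        assert llr(0, 17)[0] == 0.0
        assert llr(23, 0)[0] == 1.0

    def test_no_needles_gives_reason(self):
        value, reason = llr(0, 0)
        assert np.isnan(value) and "zero" in reason

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            llr(-1, 5)


class TestClassifySeverity:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (0.75, "healthy"), (0.7, "light"), (0.6, "light"), (0.5, "light"),
            (0.49, "moderate"), (0.1, "moderate"), (0.05, "severe"),
        ],
    )
    def test_fresh_weight_scale(self, value, expected):
        code = classify_severity(value, LWCF_SCHEME)
        assert SEVERITY_CLASSES[code] == expected

    @pytest.mark.parametrize(
        "value, expected",
        [(2.5, "healthy"), (2.1, "light"), (1.0, "light"), (0.55, "moderate"),
         (0.1, "moderate"), (0.05, "severe")],
    )
    def test_dry_weight_scale(self, value, expected):
        code = classify_severity(value, LWCD_SCHEME)
        assert SEVERITY_CLASSES[code] == expected

    @pytest.mark.parametrize(
        "value, expected",
        [(0.0, "healthy"), (0.05, "healthy"), (0.2, "light"), (0.3, "light"),
         (0.5, "moderate"), (0.7, "moderate"), (0.9, "severe")],
    )
    def test_leaf_loss_scale(self, value, expected):
        code = classify_severity(value, LLR_SCHEME)
        assert SEVERITY_CLASSES[code] == expected

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            classify_severity(-0.1, LWCF_SCHEME)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=20))
    def test_monotone_in_water_content(self, values):
        # higher water content never maps to a more severe class
        v = np.sort(np.asarray(values))
        codes = classify_severity(v, LWCF_SCHEME)
        assert np.all(np.diff(codes) <= 0)


class TestMapDamage:
    def test_constant_healthy_raster(self):
        raster = np.full((5, 5), 0.75)
        classes, counts = map_damage(raster, LWCF_SCHEME)
        assert counts["healthy"] == 25
        assert sum(counts.values()) == 25

    def test_counts_conserved_under_mask(self):
        rng = np.random.default_rng(0)
        raster = rng.uniform(0, 1, (10, 10))
        mask = rng.uniform(size=(10, 10)) > 0.4
        _, counts = map_damage(raster, LWCF_SCHEME, mask=mask)
        assert sum(counts.values()) == int(mask.sum())

    def test_toy_raster_cell_by_cell(self):
        raster = np.array([[0.75, 0.6], [0.3, 0.05]])
        classes, _ = map_damage(raster, LWCF_SCHEME)
        for (i, j), v in np.ndenumerate(raster):
            assert classes[i, j] == classify_severity(v, LWCF_SCHEME)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mpty"):
            map_damage(np.ones((3, 3)), LWCF_SCHEME, mask=np.zeros((3, 3), bool))


class TestConfusion:
    def test_identity(self):
        labels = np.array([0, 1, 2, 3, 2, 1])
        cs = confusion(labels, labels)
        assert cs.oa == 1.0 and cs.kappa == pytest.approx(1.0)
        present = np.unique(labels)
        assert all(cs.ua[c] == 1.0 and cs.pa[c] == 1.0 for c in present)

    def test_hand_computed_two_class_summary(self):
        # prediction-side counts: 17 predicted class 0 (15 right), 25
        # predicted class 1 (20 right); reference has 20 of class 0.
        ref = np.array([0] * 15 + [1] * 2 + [0] * 5 + [1] * 20)
        pred = np.array([0] * 17 + [1] * 25)
        cs = confusion(pred, ref, classes=[0, 1])
        assert cs.oa == pytest.approx(35 / 42)
        assert cs.ua[0] == pytest.approx(15 / 17)
        assert cs.pa[0] == pytest.approx(15 / 20)
        # brute-force kappa from marginals
        n = 42
        pe = (20 * 17 + 22 * 25) / n**2
        assert cs.kappa == pytest.approx((35 / 42 - pe) / (1 - pe))

    def test_single_class_degenerate_kappa_is_flagged(self):
        labels = np.zeros(10, int)
        cs = confusion(labels, labels, classes=[0])
        assert np.isnan(cs.kappa) and cs.kappa_reason is not None

    def test_label_outside_scheme_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion([0, 9], [0, 1], classes=[0, 1, 2, 3])

    def test_water_and_leaf_loss_classifiers_agree_beyond_chance(self, default_plots):
        # the two severity readings of the same synthetic cohort should
        # agree better than chance at default coupling
        water = classify_severity(default_plots["LWCF"].to_numpy(), LWCF_SCHEME)
        loss = classify_severity(default_plots["LLR"].to_numpy(), LLR_SCHEME)
        cs = confusion(water, loss)
        assert cs.kappa > 0
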