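"""Gaussian maximum-likelihood classifier against closed-form oracles."""

import numpy as np
import pytest
from scipy import stats

from larchwc.geo import Affine
from larchwc.landcover import (
    NODATA_LABEL,
    classify_mlc,
    fit_mlc,
    forest_mask,
    map_accuracy,
)
from larchwc.scene import ALL_BANDS, SpectralScene


def _scene_from_stack(stack):
    h, w = stack.shape[1:]
    bands = {b: stack[i] for i, b in enumerate(ALL_BANDS[: stack.shape[0]])}
    return SpectralScene(
        bands=bands,
        transform=Affine.from_origin(0, h * 10.0, 10.0, 10.0),
        gsd={b: 10.0 for b in bands},
    )


def _gaussian_samples(rng, mus, n=80, scale=0.01):
    X, y = [], []
    for c, mu in enumerate(mus):
        X.append(rng.normal(mu, scale, size=(n, len(mu))))
        y.append(np.full(n, c))
    return np.vstack(X), np.concatenate(y)


class TestFitMLC:
    def test_single_class_classifies_everything_as_it(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0.3, 0.01, size=(50, 10))
        model = fit_mlc(X, np.zeros(50, int))
        scene = _scene_from_stack(rng.uniform(0, 1, (10, 6, 6)))
        assert np.all(classify_mlc(model, scene) == 0)

    def test_priors_sum_to_one(self):
        rng = np.random.default_rng(1)
        X, y = _gaussian_samples(rng, [np.full(10, 0.2), np.full(10, 0.6)], n=30)
        model = fit_mlc(X, y)
        assert model.priors.sum() == pytest.approx(1.0, abs=1e-12)
        model_eq = fit_mlc(X, y, equal_priors=True)
        np.testing.assert_allclose(model_eq.priors, 0.5)

    def test_too_few_samples_names_the_class(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 10))
        y = np.array([0] * 11 + [1])
        with pytest.raises(ValueError, match="1"):
            fit_mlc(X, y)

    def test_equal_covariance_boundary_is_perpendicular_bisector(self):
        # With shared covariance and equal priors the decision boundary is
        # the hyperplane equidistant from the two means (LDA geometry).
        rng = np.random.default_rng(3)
        mu0, mu1 = np.full(10, 0.2), np.full(10, 0.4)
        common = rng.normal(0, 0.02, size=(200, 10))
        X = np.vstack([common + mu0, common + mu1])  # identical sample covariance
        y = np.array([0] * 200 + [1] * 200)
        model = fit_mlc(X, y)
        m0, m1 = model.means
        mid = (m0 + m1) / 2
        direction = (m1 - m0) / np.linalg.norm(m1 - m0)
        eps = 1e-3
        g = model.discriminants(np.vstack([mid - eps * direction, mid + eps * direction]))
        assert g[0, 0] > g[0, 1]  # just on the mu0 side
        assert g[1, 1] > g[1, 0]  # just on the mu1 side


class TestClassifyMLC:
    def test_pixel_at_class_mean_gets_that_class(self):
        rng = np.random.default_rng(4)
        mus = [np.full(10, v) for v in (0.2, 0.5, 0.8)]
        X, y = _gaussian_samples(rng, mus)
        model = fit_mlc(X, y)
        stack = np.zeros((10, 1, 3))
        for c, mu in enumerate(mus):
            stack[:, 0, c] = mu
        labels = classify_mlc(model, _scene_from_stack(stack))
        np.testing.assert_array_equal(labels[0], [0, 1, 2])

    def test_symmetric_midpoint_tie_takes_first_class(self):
        # exact tie constructed directly: identical covariances/priors,
        # pixel equidistant from both means
        from larchwc.landcover import MLCModel

        # dyadic values so the midpoint is an exact floating-point tie
        mu0, mu1 = np.full(10, 0.25), np.full(10, 0.75)
        cov = np.eye(10) * 4e-4
        model = MLCModel(
            classes=[0, 1],
            means=np.vstack([mu0, mu1]),
            covariances=np.stack([cov, cov.copy()]),
            priors=np.array([0.5, 0.5]),
        )
        stack = ((mu0 + mu1) / 2).reshape(10, 1, 1)
        assert classify_mlc(model, _scene_from_stack(stack))[0, 0] == 0

    def test_agrees_with_direct_gaussian_density_oracle(self):
        rng = np.random.default_rng(6)
        mus = [rng.uniform(0.1, 0.9, 10) for _ in range(3)]
        X, y = _gaussian_samples(rng, mus, n=100, scale=0.05)
        model = fit_mlc(X, y)
        pixels = rng.uniform(0, 1, size=(100, 10))
        scene = _scene_from_stack(pixels.T.reshape(10, 10, 10))
        got = classify_mlc(model, scene).ravel()
        # oracle: explicit log-density + log-prior per class
        scores = np.column_stack([
            stats.multivariate_normal.logpdf(pixels, mean=model.means[c],
                                             cov=model.covariances[c])
            + np.log(model.priors[c])
            for c in range(3)
        ])
        np.testing.assert_array_equal(got, np.argmax(scores, axis=1))

    def test_non_finite_pixels_become_nodata(self):
        rng = np.random.default_rng(7)
        X, y = _gaussian_samples(rng, [np.full(10, 0.3), np.full(10, 0.6)])
        model = fit_mlc(X, y)
        stack = rng.uniform(0, 1, (10, 4, 4))
        stack[0, 1, 1] = np.nan
        labels = classify_mlc(model, _scene_from_stack(stack))
        assert labels[1, 1] == NODATA_LABEL
        assert np.all(labels[0] != NODATA_LABEL)

    def test_rescaling_invariance_when_refit(self):
        rng = np.random.default_rng(8)
        mus = [rng.uniform(0.2, 0.8, 10) for _ in range(3)]
        X, y = _gaussian_samples(rng, mus, n=60, scale=0.04)
        stack = rng.uniform(0, 1, (10, 8, 8))
        base = classify_mlc(fit_mlc(X, y), _scene_from_stack(stack))
        rescaled = classify_mlc(fit_mlc(3.0 * X + 0.1, y), _scene_from_stack(3.0 * stack + 0.1))
        np.testing.assert_array_equal(base, rescaled)


class TestMapAccuracy:
    def test_identical_maps_score_perfectly(self):
        ref = np.array([[0, 1], [2, 1]])
        cs = map_accuracy(ref, ref)
        assert cs.oa == 1.0 and cs.kappa == pytest.approx(1.0)

    def test_hand_computed_two_class_matrix(self):
        ref = np.array([0, 0, 0, 1, 1, 1]).reshape(2, 3)
        pred = np.array([0, 0, 1, 0, 1, 1]).reshape(2, 3)
        cs = map_accuracy(pred, ref)
        np.testing.assert_array_equal(cs.matrix, [[2, 1], [1, 2]])
        assert cs.oa == pytest.approx(4 / 6)
        assert cs.kappa == pytest.approx(1 / 3)  # p_e = 0.5

    def test_label_swap_gives_non_positive_kappa(self):
        ref = np.array([[0] * 4 + [1] * 4])
        cs = map_accuracy(1 - ref, ref)
        assert cs.kappa <= 0

    def test_marginals_conserve_cell_count(self):
        rng = np.random.default_rng(9)
        ref = rng.integers(0, 3, (20, 20))
        pred = rng.integers(0, 3, (20, 20))
        cs = map_accuracy(pred, ref)
        assert cs.matrix.sum() == 400
        assert -1 <= cs.kappa <= 1 and 0 <= cs.oa <= 1

    def test_zero_overlap_raises(self):
        ref = np.full((3, 3), NODATA_LABEL)
        with pytest.raises(ValueError, match="overlap"):
            map_accuracy(ref, ref)


class TestForestMask:
    def test_counts(self):
        labels = np.array([[0, 1], [0, 2]])
        assert forest_mask(labels).sum() == 2
        assert forest_mask(np.full((3, 3), 4)).sum() == 0
        assert forest_mask(np.zeros((3, 3), int)).sum() == 9
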