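"""Unmixing chain against brute-force and constructed oracles."""

import numpy as np
import pytest

from larchwc.synthetic import default_endmember_library
from larchwc.unmixing import (
    align_endmembers,
    estimate_noise,
    fcls,
    hysime,
    spectral_angle,
    vca,
)

E_LIB = default_endmember_library().matrix()  # (10, 3)


def _random_simplex(rng, k, n):
    a = rng.dirichlet(np.ones(k), size=n).T
    return a


def _mixture_data(rng, n=1000, sigma=0.0, k=3):
    A = _random_simplex(rng, k, n)
    X = E_LIB[:, :k] @ A
    if sigma > 0:
        X = X + rng.normal(0, sigma, X.shape)
    return X, A


class TestEstimateNoise:
    def test_noiseless_subspace_data_has_zero_residuals(self):
        rng = np.random.default_rng(0)
        X, _ = _mixture_data(rng, n=500)
        noise, Rn = estimate_noise(X)
        assert np.max(np.abs(noise)) < 1e-8

    def test_white_noise_variance_recovered(self):
        # Monte-Carlo at 40 bands: the estimator's errors-in-variables
        # bias scales as rank/(bands-1), so a hyperspectral-sized band
        # count is needed for a tight variance check.
        rng = np.random.default_rng(1)
        B = rng.uniform(0.1, 0.9, (40, 3))
        A = rng.dirichlet(np.ones(3), 5000).T
        X = B @ A + rng.normal(0, 0.01, (40, 5000))
        _, Rn = estimate_noise(X)
        est_var = float(np.mean(np.diag(Rn)))
        assert est_var == pytest.approx(1e-4, rel=0.2)

    def test_single_band_is_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise(np.ones((1, 100)))


class TestHysime:
    def test_three_dim_subspace_gives_k_three(self):
        rng = np.random.default_rng(2)
        X, _ = _mixture_data(rng, n=2000, sigma=1e-4)
        noise, _ = estimate_noise(X)
        k, basis = hysime(X, noise)
        assert k == 3
        assert basis.shape == (10, 3)

    def test_pure_white_noise_floors_at_k_of_at_most_one(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 0.01, (10, 2000))
        noise, _ = estimate_noise(X)
        k, _ = hysime(X, noise)
        assert k <= 1

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            hysime(np.ones((5, 100)), np.ones((5, 99)))


class TestVCA:
    def test_pure_pixels_recovered_exactly(self):
        rng = np.random.default_rng(4)
        X = np.repeat(E_LIB, 50, axis=1)  # 3 pure spectra, repeated
        ems = vca(X, 3, seed=0)
        perm = align_endmembers(ems.spectra, E_LIB)
        for j in range(3):
            assert spectral_angle(ems.spectra[:, perm[j]], E_LIB[:, j]) < 1e-10

    def test_interior_mixtures_pick_vertex_most_points(self):
        # Mixtures shrunk toward the centroid by factor (1 - rho): the best
        # achievable endmember is the shrunk vertex itself.
        rng = np.random.default_rng(5)
        rho = 0.2
        A = (1 - rho) * np.eye(3) + rho / 3
        corners = E_LIB @ A  # shrunk simplex vertices
        A_int = _random_simplex(rng, 3, 500) * (1 - rho) + rho / 3
        A_int /= A_int.sum(axis=0)
        X = np.hstack([corners, E_LIB @ A_int])
        ems = vca(X, 3, seed=1)
        perm = align_endmembers(ems.spectra, E_LIB)
        shrink_angle = max(
            spectral_angle(corners[:, j], E_LIB[:, j]) for j in range(3)
        )
        for j in range(3):
            ang = spectral_angle(ems.spectra[:, perm[j]], E_LIB[:, j])
            assert ang <= shrink_angle + 1e-9

    def test_same_seed_same_selection(self):
        rng = np.random.default_rng(6)
        X, _ = _mixture_data(rng, n=400, sigma=0.002)
        a = vca(X, 3, seed=9)
        b = vca(X, 3, seed=9)
        np.testing.assert_array_equal(a.pixel_indices, b.pixel_indices)

    def test_invalid_k_raises(self):
        X = np.ones((10, 50))
        with pytest.raises(ValueError):
            vca(X, 0)
        with pytest.raises(ValueError):
            vca(X, 11)


class TestFCLS:
    def test_pure_pixel_gets_unit_abundance(self):
        for j in range(3):
            a = fcls(E_LIB[:, [j]] * np.ones((1, 1)), E_LIB)[:, 0]
            expected = np.zeros(3)
            expected[j] = 1.0
            np.testing.assert_allclose(a, expected, atol=1e-8)

    def test_even_two_way_mixture_recovered(self):
        x = (0.5 * E_LIB[:, 0] + 0.5 * E_LIB[:, 1])[:, None]
        a = fcls(x, E_LIB)[:, 0]
        np.testing.assert_allclose(a, [0.5, 0.5, 0.0], atol=1e-6)

    def test_objective_matches_simplex_grid_search(self):
        # brute-force oracle: dense grid over the 3-simplex, step 0.01
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 0.6, (10, 200))
        A = fcls(X, E_LIB)
        step = 0.01
        grid = []
        for i in range(101):
            for j in range(101 - i):
                grid.append((i * step, j * step, 1.0 - (i + j) * step))
        G = np.array(grid).T                       # (3, m)
        EG = E_LIB @ G                             # (10, m)
        # ||x - EG||^2 for all pixels/grid points
        cost = (
            np.sum(X**2, axis=0)[:, None]
            - 2 * X.T @ EG
            + np.sum(EG**2, axis=0)[None, :]
        )
        best = cost.min(axis=1)
        ours = np.sum((X - E_LIB @ A) ** 2, axis=0)
        # agreement at grid resolution: the solver's tiny augmentation
        # bias is orders below one grid step
        assert np.all(ours <= best + 1e-4)
        assert np.all(ours >= best - 3 * step)

    def test_output_on_simplex(self):
        rng = np.random.default_rng(8)
        X, _ = _mixture_data(rng, n=300, sigma=0.01)
        A = fcls(X, E_LIB)
        assert np.all(A >= 0)
        np.testing.assert_allclose(A.sum(axis=0), 1.0, atol=1e-6)

    def test_beats_best_pure_pixel_assignment(self):
        rng = np.random.default_rng(9)
        X, _ = _mixture_data(rng, n=200, sigma=0.01)
        A = fcls(X, E_LIB)
        recon = np.sum((X - E_LIB @ A) ** 2, axis=0)
        pure = np.min(
            [np.sum((X - E_LIB[:, [j]]) ** 2, axis=0) for j in range(3)], axis=0
        )
        assert np.all(recon <= pure + 1e-12)

    def test_rank_deficient_endmembers_rejected(self):
        E_bad = np.column_stack([E_LIB[:, 0], E_LIB[:, 0]])
        with pytest.raises(ValueError, match="rank"):
            fcls(np.ones((10, 5)) * 0.3, E_bad)


class TestEndToEnd:
    def test_noise_free_scene_abundances_recovered(self, default_config):
        from larchwc.synthetic import SceneConfig, generate_damage_field, generate_scene
        import dataclasses

        cfg = dataclasses.replace(default_config, noise_sigma=0.0)
        field = generate_damage_field(cfg)
        _, truth = generate_scene(field, config=cfg)
        X = np.stack([truth.bands10[b] for b in
                      ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12")])
        X = X[:, truth.forest_mask]
        ems = vca(X, 3, seed=0)
        A = fcls(X, ems.spectra)
        perm = align_endmembers(ems.spectra, truth.endmembers.matrix())
        rmse = np.sqrt(np.mean((A[perm] - truth.abundances[:, truth.forest_mask]) ** 2))
        assert rmse < 1e-3

    def test_noisy_scene_abundance_error_bounded(self, forest_pixels, default_truth):
        X = forest_pixels  # default noise_sigma = 0.005
        ems = vca(X, 3, seed=0)
        A = fcls(X, ems.spectra)
        perm = align_endmembers(ems.spectra, default_truth.endmembers.matrix())
        rmse = np.sqrt(np.mean(
            (A[perm] - default_truth.abundances[:, default_truth.forest_mask]) ** 2
        ))
        assert rmse < 0.05
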