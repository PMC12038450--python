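"""Shared fixtures: one default synthetic scene, generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from larchwc.synthetic import (
    SceneConfig,
    generate_damage_field,
    generate_plots,
    generate_scene,
    plot_means,
)


@pytest.fixture(scope="session")
def default_config() -> SceneConfig:
    return SceneConfig(seed=7)


@pytest.fixture(scope="session")
def scene_and_truth(default_config):
    field = generate_damage_field(default_config)
    return generate_scene(field, config=default_config)


@pytest.fixture(scope="session")
def default_scene(scene_and_truth):
    return scene_and_truth[0]


@pytest.fixture(scope="session")
def default_truth(scene_and_truth):
    return scene_and_truth[1]


@pytest.fixture(scope="session")
def default_trees(default_config, default_truth):
    field = generate_damage_field(default_config)
    return generate_plots(field, default_config, mask=default_truth.forest_mask)


@pytest.fixture(scope="session")
def default_plots(default_trees):
    return plot_means(default_trees)


@pytest.fixture(scope="session")
def forest_pixels(default_scene, default_truth):
    """(bands x pixels) matrix of the noisy 10 m truth under the forest mask."""
    stack = np.stack([default_truth.bands10[b] for b in default_scene.band_names])
    return stack[:, default_truth.forest_mask]
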