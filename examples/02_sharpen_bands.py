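"""Bring the 20 m red-edge/SWIR bands onto the 10 m grid.

Sharpens a synthetic scene with the consistency-constrained local
regression and verifies the radiometric contract: every 2x2 block mean
of a sharpened band reproduces the original 20 m observation.
"""

import numpy as np

from larchwc.scene import block_mean
from larchwc.sharpening import SharpenConfig, sharpen_scene
from larchwc.synthetic import SceneConfig, generate_damage_field, generate_scene

cfg = SceneConfig(seed=42)
scene, truth = generate_scene(generate_damage_field(cfg), config=cfg)
scene10 = sharpen_scene(scene, SharpenConfig(window=15, ridge=1e-3))

for band in ("B5", "B11"):
    err_vs_truth = np.sqrt(np.mean((scene10.bands[band] - truth.bands10[band]) ** 2))
    consistency = np.max(np.abs(block_mean(scene10.bands[band], 2) - scene.bands[band]))
    naive = np.sqrt(np.mean(
        (np.kron(scene.bands[band], np.ones((2, 2))) - truth.bands10[band]) ** 2
    ))
    print(f"{band}: RMSE vs 10 m truth {err_vs_truth:.5f} "
          f"(plain replication {naive:.5f}), block-consistency error {consistency:.1e}")

# The sharpened bands sit closer to the hidden 10 m truth than simple
# block replication, while their 20 m block means match the input to
# machine precision.
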