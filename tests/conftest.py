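"""Shared fixtures: small synthetic scenes and a no-resize config.

Unit tests run on small frames (2 plants, ~256x320) so the whole suite
stays fast; the acceptance tests use full 640x512 scenes.
"""

import numpy as np
import pytest

from phenoleaf import PipelineConfig, SceneSpec, generate_scene


@pytest.fixture
def config():
    """Pipeline defaults, but without halving (scenes are rendered at
    working resolution already)."""
    return PipelineConfig(resize=False)


@pytest.fixture
def night_scene():
    """A small, easy night frame: two well-separated 6-leaf rosettes."""
    spec = SceneSpec(
        height=256, width=320, n_plants=2, leaves_per_plant=6, seed=11
    )
    return generate_scene(spec)


@pytest.fixture
def day_scene():
    """Same layout as a day frame: gradient plus shadows over plants."""
    spec = SceneSpec(
        height=256,
        width=320,
        n_plants=2,
        leaves_per_plant=6,
        seed=11,
        illumination="day_gradient",
    )
    return generate_scene(spec)


def rgb(gray2d):
    """Replicate a 2-D uint8 array into an (H, W, 3) RGB image."""
    g = np.asarray(gray2d, dtype=np.uint8)
    return np.repeat(g[..., None], 3, axis=2)
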