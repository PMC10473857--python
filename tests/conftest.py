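import numpy as np
import pytest

from grainsight.synthetic_scenes import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A 40-grain isolated-grain scene shared across read-only tests."""
    spec = SceneSpec(width=512, height=512, n_grains=40, adhesion_prob=0.0, seed=7)
    image, gt = generate_scene(spec)
    return spec, image, gt


@pytest.fixture(scope="session")
def adhesion_scene():
    """A default-condition scene with adhesion clusters."""
    spec = SceneSpec(seed=12)
    image, gt = generate_scene(spec)
    return spec, image, gt


def min_area_of(spec: SceneSpec) -> int:
    return int(round(0.05 * spec.expected_grain_area))
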