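import numpy as np
import pytest

from aquacolor.checkerboard import CheckerboardLayout
from aquacolor.classifier import PaletteConfig
from aquacolor.synthetic import SceneSpec, render_scene


@pytest.fixture(scope="session")
def layout():
    return CheckerboardLayout()

@pytest.fixture(scope="session")
def palette():
    return PaletteConfig()


@pytest.fixture(scope="session")
def scene_bundle():
    """One default synthetic pond scene (green water, mild distortion)."""
    return render_scene(SceneSpec(seed=11))


@pytest.fixture(scope="session")
def clean_scene_bundle():
    """Identity distortion, zero noise: renderer self-check conditions."""
    spec = SceneSpec(seed=7, distortion=np.eye(3), noise_sigma=0.0)
    return render_scene(spec)
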