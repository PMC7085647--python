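import numpy as np
import pytest

from floralquant import CropSensorProfile, RasterImage, SceneParams, generate_plot_image


@pytest.fixture(scope="session")
def pea_profile():
    return CropSensorProfile.builtin("pea")


@pytest.fixture(scope="session")
def canola_profile():
    return CropSensorProfile.builtin("canola")


@pytest.fixture(scope="session")
def pea_scene():
    """One clean white-flower scene with its exact ground truth."""
    return generate_plot_image(SceneParams(flower_count=20, seed=42))


@pytest.fixture(scope="session")
def noisy_pea_scene():
    """White-flower scene with straw lines and off-canopy soil glints."""
    return generate_plot_image(
        SceneParams(flower_count=20, straw_count=8, glint_count=4, seed=43)
    )


def solid_color_image(color, shape=(8, 8), scale="raw_8bit"):
    px = np.tile(np.asarray(color, float), (*shape, 1))
    return RasterImage(px, bands=("R", "G", "B"), scale=scale)
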