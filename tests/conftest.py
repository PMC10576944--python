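import numpy as np
import pytest

from dabquant import ClassifierParams, ImageSpec, StainVectors, render_image


@pytest.fixture(scope="session")
def default_params() -> ClassifierParams:
    return ClassifierParams()


@pytest.fixture(scope="session")
def default_vectors() -> StainVectors:
    return StainVectors()


@pytest.fixture(scope="session")
def noise_free_sample():
    """A rendered image with exact ground truth and no camera noise."""
    spec = ImageSpec(
        width=96,
        height=96,
        target_fractions=(0.2, 0.1, 0.1),
        tissue_fraction=0.75,
        noise_sd=0.0,
        seed=42,
    )
    image, truth = render_image(spec)
    return spec, image, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
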