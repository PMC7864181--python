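import numpy as np
import pytest

from ifcmms import Ellipse, GrayImage, PhantomSpec, make_phantom


@pytest.fixture
def two_value_image():
    """Factory: seeded 16x16 image with values {10, 200}."""

    def build(seed: int) -> GrayImage:
        rng = np.random.default_rng(seed)
        px = np.where(rng.random((16, 16)) < 0.5, 10, 200).astype(np.uint8)
        if px.min() == px.max():  # pragma: no cover - vanishingly unlikely
            px[0, 0] = 10 if px[0, 1] == 200 else 200
        return GrayImage(px, 255)

    return build


@pytest.fixture
def two_blob_spec():
    """Noiseless two-class phantom: dark background, one bright blob."""

    def build(seed: int, shape=(64, 64)) -> PhantomSpec:
        return PhantomSpec(
            shape=shape,
            class_means=(40.0, 200.0),
            class_noise_sd=0.0,
            geometry=(Ellipse(center=(0.5, 0.5), radii=(0.3, 0.25), label=1),),
            seed=seed,
        )

    return build


@pytest.fixture
def small_phantom():
    """Default-geometry phantom at reduced size for fast iteration tests."""

    def build(seed: int, shape=(64, 64)):
        return make_phantom(PhantomSpec(shape=shape, seed=seed))

    return build
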