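import numpy as np
import pytest

from igloo import ColonySpec, SynthConfig, generate_plate


def exact_area_mask(n_pixels: int, shape=(200, 200)) -> np.ndarray:
    """A connected mask with exactly n_pixels set (raster-order fill)."""
    flat = np.zeros(shape[0] * shape[1], dtype=bool)
    flat[:n_pixels] = True
    return flat.reshape(shape)


@pytest.fixture(scope="session")
def small_plate():
    """Noiseless 512-px synthetic plate with one colony (r=65, halo r=90)."""
    cfg = SynthConfig(
        image_size_px=512,
        dish_margin_px=18,
        colonies=(ColonySpec((255.5, 255.5), 65.0, 90.0),),
        seed=7,
    )
    image, truth = generate_plate(cfg)
    return cfg, image, truth


@pytest.fixture(scope="session")
def noisy_plate():
    """Same geometry as small_plate but with mild sensor noise."""
    cfg = SynthConfig(
        image_size_px=512,
        dish_margin_px=18,
        colonies=(ColonySpec((255.5, 255.5), 65.0, 90.0),),
        noise_sd=0.02,
        illumination_gradient=0.05,
        seed=11,
    )
    image, truth = generate_plate(cfg)
    return cfg, image, truth


@pytest.fixture
def paper_area_masks():
    """Colony/halo mask pair with the reported pixel areas 13,329 / 25,571."""
    return exact_area_mask(13_329), exact_area_mask(25_571)
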