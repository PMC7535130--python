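import numpy as np
import pytest

from gfkuts import BandRaster, SceneSpec, generate_scene, stack_scene


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_scene(values_by_band, mask=None, order=None):
    """Scene from raw per-band arrays."""
    bands = {name: BandRaster(np.asarray(v, dtype=np.float64), name)
             for name, v in values_by_band.items()}
    return stack_scene(bands, composite_order=order, ground_truth_mask=mask)


def two_tone_scene(shape=(20, 20), canopy_frac=0.5, noise=0.0, seed=0):
    """Simple separable scene: left part soil-coloured, right part canopy."""
    H, W = shape
    rng = np.random.default_rng(seed)
    split = int(W * (1 - canopy_frac))
    mask = np.zeros((H, W), dtype=np.uint8)
    mask[:, split:] = 1
    means = dict(red=(0.30, 0.08), green=(0.25, 0.15), nir=(0.10, 0.60), red_edge=(0.12, 0.40))
    bands = {}
    for name, (soil, canopy) in means.items():
        v = np.where(mask == 1, canopy, soil).astype(np.float64)
        if noise:
            v = np.clip(v + rng.normal(0, noise, (H, W)), 0, 1)
        bands[name] = v
    return make_scene(bands, mask=mask)


@pytest.fixture
def separable_scene():
    return two_tone_scene()


@pytest.fixture
def clean_synthetic_scene():
    return generate_scene(SceneSpec(shape=(96, 96), canopy_fraction=0.6, noise_sd=0.02, seed=5))
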