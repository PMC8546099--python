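import numpy as np
import pytest

import grainmorph as gm
from grainmorph.segmentation import BinaryMask, extract_regions


def mask_from_bool(arr: np.ndarray) -> BinaryMask:
    return BinaryMask(values=(np.asarray(arr, bool).astype(np.uint8) * 255))


def single_region(arr: np.ndarray, min_area: float = 0.0):
    """Extract the one region of a boolean mask (padded for tracing safety)."""
    regions = extract_regions(mask_from_bool(arr), min_area)
    assert len(regions) == 1
    return regions[0]


def disk_mask(radius: int, pad: int = 3) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:n, :n] - (radius + pad)
    return yy**2 + xx**2 <= radius**2


def square_mask(side: int, pad: int = 3) -> np.ndarray:
    n = side + 2 * pad
    m = np.zeros((n, n), bool)
    m[pad : pad + side, pad : pad + side] = True
    return m


def ellipse_mask(semi_major: float, semi_minor: float, pad: int = 3) -> np.ndarray:
    n = 2 * (int(np.ceil(semi_major)) + pad) + 1
    c = n // 2
    yy, xx = np.mgrid[:n, :n]
    return ((xx - c) / semi_major) ** 2 + ((yy - c) / semi_minor) ** 2 <= 1.0


@pytest.fixture(scope="session")
def clean_sound_scene():
    """A fully noise-free 100-kernel sound scene (exact ground truth)."""
    return gm.sample_class_scene(
        "sound", 100, seed=11, rgb_noise_sd=0.0,
        boundary_irregularity=0.0, color_sd_scale=0.0,
    )


@pytest.fixture(scope="session")
def clean_sound_result(clean_sound_scene):
    image = gm.scene_to_grain_image(clean_sound_scene)
    return gm.extract_features(image)


@pytest.fixture(scope="session")
def small_noisy_scene():
    """A small scene with default texture noise, for colour/texture tests."""
    return gm.sample_class_scene("sound", 9, seed=7)


@pytest.fixture(scope="session")
def small_noisy_result(small_noisy_scene):
    return gm.extract_features(gm.scene_to_grain_image(small_noisy_scene))
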