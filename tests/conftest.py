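import numpy as np
import pytest

from fgsquant import PhantomSpec, RegionMask, mirror_roi


@pytest.fixture
def noiseless_spec():
    return PhantomSpec(gaussian_noise_sd=0.0, ppix_color_jitter_sd=0.0)


@pytest.fixture
def default_spec():
    return PhantomSpec()


@pytest.fixture
def small_spec():
    """Quarter-size section for speed-sensitive simulation tests."""
    return PhantomSpec(image_height=96, image_width=96, midline_col=48,
                       tumor_center=(48, 72), tumor_axes=(14, 10))


def gt_masks(section):
    """Ground-truth tumor mask and its mirrored contralateral ROI."""
    tumor = RegionMask(section.ground_truth_mask, "tumor")
    normal = mirror_roi(tumor, section.midline_col)
    return tumor, normal


def iou(a: np.ndarray, b: np.ndarray) -> float:
    return (a & b).sum() / (a | b).sum()
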