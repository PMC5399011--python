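import datetime as dt

import numpy as np
import pytest

from petex.core_io import AcquisitionMeta, ScalarVolume, VoiMask, VolumeUnits
from petex.preprocess import quantize

PET_SPACING = (4.7, 4.7, 3.27)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def meta_early():
    t0 = dt.datetime(2016, 1, 1, 9, 0, 0)
    return AcquisitionMeta(
        injected_activity_mbq=350.0,
        injection_time=t0,
        scan_time=t0 + dt.timedelta(minutes=101.5),
        body_weight_kg=70.0,
    )


@pytest.fixture
def cube_volume(rng):
    """12x12x10 random activity volume on the PET grid."""
    data = rng.gamma(4.0, 1500.0, size=(12, 12, 10))
    return ScalarVolume(data, PET_SPACING, units=VolumeUnits.ACTIVITY_BQ_ML)


@pytest.fixture
def cube_mask(cube_volume):
    arr = np.zeros(cube_volume.shape, dtype=bool)
    arr[2:10, 2:10, 2:8] = True
    return VoiMask(arr, cube_volume.spacing, cube_volume.origin)


def random_quantized_voi(rng, shape=(4, 4, 3), n_bins=8, voi_fraction=0.8):
    """Random small quantized VOI with an irregular mask, for matrix tests."""
    mask = rng.random(shape) < voi_fraction
    if not mask.any():
        mask.flat[0] = True
    values = rng.random(int(mask.sum()))
    idx = np.argwhere(mask)
    return quantize(values, n_bins=n_bins, indices=idx, spacing=PET_SPACING)


def constant_quantized_voi(shape=(4, 4, 3), n_bins=64):
    mask = np.ones(shape, dtype=bool)
    values = np.full(int(mask.sum()), 7.5)
    return quantize(values, n_bins=n_bins, indices=np.argwhere(mask), spacing=PET_SPACING)
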