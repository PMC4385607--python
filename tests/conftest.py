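import numpy as np
import pytest

import wmtex as w


@pytest.fixture()
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture()
def small_volume(rng):
    """Random 16x16x4 volume with a full interior mask."""
    vol = rng.normal(loc=100.0, scale=10.0, size=(16, 16, 4))
    mask = np.zeros(vol.shape, dtype=bool)
    mask[5:11, 5:11, :] = True
    return vol, mask


@pytest.fixture(scope="session")
def lesion_volume():
    """Synthetic FLAIR-like volume with known lesion ground truth."""
    rng = np.random.default_rng(7)
    return w.generate_volume(
        (48, 48, 8),
        w.TextureParams(mean=100.0, sigma=5.0, corr_length=1.5),
        lesions=w.LesionParams(count=3, radius_range=(2.0, 4.0), contrast=2.0),
        rng=rng,
    )


@pytest.fixture(scope="session")
def imbalanced_table():
    """Gaussian feature table with the 57/16/36 class design."""
    rng = np.random.default_rng(99)
    X = rng.normal(size=(57 + 16 + 36, 6))
    y = ["AD"] * 57 + ["LBD"] * 16 + ["NC"] * 36
    return w.CohortTable.from_arrays(X, y)
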