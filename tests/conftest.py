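import numpy as np
import pytest

from connectopy.io import extract_roi_series
from connectopy.phantom import PhantomSpec, generate_phantom


def run_extract(spec):
    """Generate a phantom and return (X, voxel_table, roi_columns, truth)."""
    bold, roi, brain, truth = generate_phantom(spec)
    X, table = extract_roi_series(bold, brain)
    roi_cols = roi[table["i"].to_numpy(), table["j"].to_numpy(), table["k"].to_numpy()]
    return X, table, roi_cols, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Standard validation phantom: 6x6x10 ROI, K=4 networks, T=200, sd 0.5."""
    return run_extract(PhantomSpec(seed=0, noise_sd=0.5))


@pytest.fixture(scope="session")
def noise_free_phantom():
    return run_extract(PhantomSpec(seed=0, noise_sd=0.0))
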