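import numpy as np
import pytest

from selfrsa import synthgen
from selfrsa.iohub import MaskVolume, isotropic_affine


@pytest.fixture(scope="session")
def small_mask() -> MaskVolume:
    """Desk-scale ellipsoid mask (~800 voxels) with genuine boundary."""
    return synthgen.ellipsoid_mask((14, 16, 14))


@pytest.fixture(scope="session")
def box_mask() -> MaskVolume:
    """A 6x6x6 box inside a 10x10x10 grid: simple support for null
    simulations where cluster geometry matters but mask shape does not."""
    data = np.zeros((10, 10, 10), dtype=bool)
    data[2:8, 2:8, 2:8] = True
    return MaskVolume(data, isotropic_affine(3.0))


@pytest.fixture(scope="session")
def exp1_cohort(small_mask):
    """Eight participants with self-importance geometry embedded in a
    spherical ROI, self task only (the reference ground-truth setup)."""
    ratings, cohort, truth = synthgen.generate_cohort(
        8, small_mask, encoding_dimension="self_importance",
        effect=1.0, noise_sd=1.0, n_items=40, n_runs=6,
        tasks=("self", "word"), seed=20230517)
    return ratings, cohort, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
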