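import numpy as np
import pytest

from bsabind import GroundTruth, simulate_titration


@pytest.fixture
def exact_truth():
    """Noise-free, inner-filter-free ground truth: closed-form titrations."""
    return GroundTruth(kb=4.592e4, n=1.08, ife_ex=0.0, ife_em=0.0, noise_sd=0.0)


@pytest.fixture
def exact_series(exact_truth):
    return simulate_titration(exact_truth)


@pytest.fixture
def ife_truth():
    """Noise-free but with inner-filter attenuation recorded per point."""
    return GroundTruth(kb=4.592e4, n=1.08, noise_sd=0.0)


@pytest.fixture
def micromolar_grid():
    """The default titration design: 5 µM protein at molar ratios 0-6."""
    return np.array([0.0, 5e-6, 7.5e-6, 1e-5, 1.5e-5, 2e-5, 2.5e-5, 3e-5])
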