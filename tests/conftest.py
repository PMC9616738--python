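import numpy as np
import pytest

import pose2thal as p2t


@pytest.fixture(scope="session")
def model():
    return p2t.default_shape_model()


@pytest.fixture(scope="session")
def exact_model():
    """Shape model with (numerically) zero residual noise, for noise-free
    generative-identity checks where ridge shrinkage must vanish."""
    return p2t.default_shape_model(noise_variance=1e-8)


@pytest.fixture(scope="session")
def kinematics():
    """A 300 s ground-truth session shared across coupling tests."""
    return p2t.generate_kinematics(300.0, seed=101)


@pytest.fixture(scope="session")
def behavior(kinematics):
    return p2t.ground_truth_behavior(kinematics)


@pytest.fixture(scope="session")
def om_covariate(kinematics, behavior):
    """Per-epoch OM series at cross-correlogram resolution."""
    bins = p2t.bin_spikes(
        np.array([]), kinematics.epochs, p2t.CC_BIN_S,
        behavior=behavior, covariate_names=("Bar", "OM"),
    )
    return bins


def random_rigid(rng):
    """A random proper rotation and translation."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, rng.normal(size=3) * 10.0
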