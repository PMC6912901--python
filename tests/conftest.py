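import numpy as np
import pytest
from hypothesis import settings

import sdmbias as sb

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_stack() -> sb.CovariateStack:
    """A 40x40 standardized 3-layer landscape used across unit tests."""
    target = np.array([[1.0, 0.2, 0.1], [0.2, 1.0, 0.15], [0.1, 0.15, 1.0]])
    return sb.generate_covariates(40, 40, 3, spatial_range=150.0,
                                  target_correlation=target, seed=7)


@pytest.fixture()
def toy_stack() -> sb.CovariateStack:
    """A tiny stack with hand-set standardized values for exact arithmetic.

    Layer values are declared standardized so log-linear intensities can be
    checked against closed-form expectations.
    """
    rng = np.random.default_rng(3)
    grids = {
        name: sb.Grid(rng.normal(size=(5, 5)), cell_size=25.0) for name in ("slope", "canopy", "simpson")
    }
    stack = sb.CovariateStack(grids)
    return sb.standardize(stack)
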