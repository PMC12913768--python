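"""Shared fixtures: small demographic histories and grids."""

import numpy as np
import pytest

from imcoal.im_model import EpochedHistory, ScalingConfig, TimeGrid


@pytest.fixture(scope="session")
def scaling() -> ScalingConfig:
    return ScalingConfig()  # mu = 7.1e-9, g = 2


@pytest.fixture(scope="session")
def small_grid() -> TimeGrid:
    """16 log-spaced boundaries: cheap fits for unit tests."""
    return TimeGrid.log_spaced(16, 10.0, 5e5)


@pytest.fixture(scope="session")
def analysis_grid() -> TimeGrid:
    """The pipeline's working grid (42 boundaries, 1e3 to 5e5 generations)."""
    return TimeGrid.log_spaced(42, 1000.0, 5e5)


@pytest.fixture(scope="session")
def constant_history() -> EpochedHistory:
    return EpochedHistory.constant(20_000.0, m=1e-5)


def random_history(rng: np.random.Generator, min_epochs: int = 2,
                   max_epochs: int = 4) -> EpochedHistory:
    """Random small piecewise history for oracle cross-checks."""
    n_ep = int(rng.integers(min_epochs, max_epochs + 1))
    bounds = np.concatenate(
        [[0.0], np.sort(rng.uniform(500.0, 80_000.0, size=n_ep - 1))])
    return EpochedHistory(
        boundaries=bounds,
        N1=rng.uniform(1_000.0, 50_000.0, size=n_ep),
        N2=rng.uniform(1_000.0, 50_000.0, size=n_ep),
        m=rng.choice([0.0, 1e-5, 1e-4, 1e-3], size=n_ep),
    )
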