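import numpy as np
import pytest

from qcsf.engine import (
    LikelihoodCache,
    ParameterGrid,
    StimulusSpace,
    default_parameter_grid,
    default_stimulus_space,
    init_prior,
)
from qcsf.model import CSFParameters, PsychometricSpec


@pytest.fixture(scope="session")
def spec() -> PsychometricSpec:
    return PsychometricSpec()


@pytest.fixture(scope="session")
def tiny_grid() -> ParameterGrid:
    """3x3x2x2 grid for exhaustive-oracle comparisons."""
    return ParameterGrid(
        peak_gain=np.array([5.0, 50.0, 500.0]),
        peak_frequency=np.array([1.0, 3.0, 9.0]),
        bandwidth=np.array([0.25, 0.6]),
        truncation=np.array([0.2, 1.0]),
    )


@pytest.fixture(scope="session")
def small_grid() -> ParameterGrid:
    """Coarse but usable estimation grid."""
    return default_parameter_grid(10, 8, 6, 5)


@pytest.fixture(scope="session")
def small_space() -> StimulusSpace:
    return default_stimulus_space(8, 10)


@pytest.fixture(scope="session")
def recovery_grid() -> ParameterGrid:
    """Grid for parameter-recovery simulations.

    Matches the study pipeline's scale; coarser grids hit a quantization
    bias floor (~0.09 in AULCSF) that masks the benefit of longer sessions.
    """
    return default_parameter_grid(18, 14, 9, 9)


@pytest.fixture(scope="session")
def recovery_space() -> StimulusSpace:
    return default_stimulus_space(20, 24)


@pytest.fixture(scope="session")
def recovery_cache(recovery_grid, recovery_space, spec) -> LikelihoodCache:
    return LikelihoodCache(recovery_grid, recovery_space, spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


def random_params(rng: np.random.Generator) -> CSFParameters:
    """A random but physiologically plausible CSF parameter set."""
    return CSFParameters(
        peak_gain=float(10.0 ** rng.uniform(0.5, 3.0)),
        peak_frequency=float(10.0 ** rng.uniform(-0.5, 1.2)),
        bandwidth=float(10.0 ** rng.uniform(-0.7, 0.5)),
        truncation=float(10.0 ** rng.uniform(-1.5, 0.3)),
    )
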