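import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from actihmm import (
    GaussianHMM,
    SimulationSpec,
    example_harmonic_model,
    example_homogeneous_model,
    simulate,
)


@pytest.fixture(scope="session")
def toy2():
    """Hand-specified 2-state model and short series from the worked
    likelihood example (amenable to path enumeration)."""
    model = GaussianHMM.from_params(
        delta=[0.5, 0.5],
        means=[0.0, 3.0],
        sds=[1.0, 1.0],
        transmat=[[0.9, 0.1], [0.2, 0.8]],
    )
    y = np.array([0.1, 2.9, 3.1])
    return model, y


@pytest.fixture(scope="session")
def homog2_sim():
    """Two-state homogeneous simulation used by several recovery tests."""
    truth = GaussianHMM.from_params(
        delta=[0.5, 0.5],
        means=[1.0, 5.0],
        sds=[1.0, 1.0],
        transmat=[[0.95, 0.05], [0.05, 0.95]],
    )
    res = simulate(
        SimulationSpec(model=truth, n_days=10_000 * 300 / 86_400, seed=11)
    )
    return truth, res


@pytest.fixture(scope="session")
def strong_sim():
    """Fourteen days of 5-min epochs from the strong-rhythm subject."""
    truth = example_harmonic_model("strong")
    return truth, simulate(SimulationSpec(model=truth, n_days=14, seed=0))


@pytest.fixture(scope="session")
def homog3_fit(strong_sim):
    """A converged homogeneous 3-state fit on realistic synthetic data."""
    _, res = strong_sim
    return GaussianHMM(n_states=3, n_starts=3, random_state=0).fit(res.series), res
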