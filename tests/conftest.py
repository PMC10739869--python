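import numpy as np
import pytest

import debyesim as ds


@pytest.fixture(scope="session")
def n4_model() -> ds.DebyeMultipole:
    """Published 4-pole potato-tissue parameterisation."""
    return ds.fixture_models()["n4"]


@pytest.fixture(scope="session")
def cylinder() -> ds.SampleGeometry:
    """The study sample: 18.50 mm diameter, 5 mm high."""
    return ds.STUDY_CYLINDER


@pytest.fixture(scope="session")
def sweep_grid() -> np.ndarray:
    """40 Hz - 10 MHz, 20 points/decade measurement grid."""
    return ds.default_frequency_grid()


def random_debye_model(rng: np.random.Generator,
                       max_poles: int = 4) -> ds.DebyeMultipole:
    """Random valid model inside the fitting bounds (shared test helper)."""
    n = int(rng.integers(0, max_poles + 1))
    poles = tuple(
        ds.DebyePole(10.0 ** rng.uniform(-3, 8), 10.0 ** rng.uniform(-12, 1))
        for _ in range(n)
    )
    return ds.DebyeMultipole(
        sigma_s=10.0 ** rng.uniform(-4, 0),
        eps_inf=10.0 ** rng.uniform(0, 8),
        poles=poles,
    )
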