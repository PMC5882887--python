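import numpy as np
import pytest

from grnest.fixtures import random_stable_model
from grnest.lmi import minimize_gamma
from grnest.model import SectorBounds


@pytest.fixture(scope="session")
def toy_model():
    """Seeded random contraction model used across the LMI/verify tests."""
    return random_stable_model(seed=1, n=2, target_contraction=0.3)


@pytest.fixture(scope="session")
def hill_sector():
    return SectorBounds.for_hill(2, h=2.0)


@pytest.fixture(scope="session")
def toy_synthesis(toy_model, hill_sector):
    """Repaired-mode synthesis with minimized attenuation on the toy model.

    Computed once per session; the end-to-end synthesis, the re-substitution
    check, and the Monte-Carlo consistency checks all consume it.
    """
    gamma, result = minimize_gamma(
        toy_model, hill_sector, fidelity="repaired", seed=0
    )
    assert result.status == "feasible"
    return gamma, result
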