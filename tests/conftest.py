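import numpy as np
import pytest

import agecult as ac


@pytest.fixture
def spread_config():
    """Baseline trait-spread parameterization (default preset)."""
    return ac.load_config()


@pytest.fixture
def contrast_config():
    """Selected-versus-neutral contrast demography (b=4, heavier survival)."""
    return ac.load_config(preset="fitness_contrast")


@pytest.fixture
def uniform_state():
    """Uniform 100-individual state with the trait at 0.005 everywhere."""
    return ac.generate_fixture("uniform", 100.0, 0.005)


@pytest.fixture
def demo_params():
    return ac.DemographyParams(b=5.0, s=(0.5, 0.6, 0.6, 0.6, 0.2), w_f=1.0, w_s=0.05)


def make_state(n, x, history=()):
    return ac.PopulationState.from_counts(
        np.asarray(n, float), np.asarray(x, float), adult_freq_history=history
    )
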