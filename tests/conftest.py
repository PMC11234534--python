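import numpy as np
import pytest

from predsize.dgm import equal_strength_spec, main_study_spec
from predsize.scenario import calibrate_scenario


@pytest.fixture(scope="session")
def example_spec():
    """The 24-equal-strength-predictor worked-example scenario."""
    return equal_strength_spec(0.174, 0.89, 24)


@pytest.fixture(scope="session")
def example_model(example_spec):
    return calibrate_scenario(example_spec)


@pytest.fixture(scope="session")
def main_spec_weak():
    """Main 12-predictor design at low model strength."""
    return main_study_spec(0.3, 0.7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240710)
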