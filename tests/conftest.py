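import numpy as np
import pytest

import locmix as lm


@pytest.fixture(scope="session")
def screen() -> lm.ScreenGeometry:
    return lm.DEFAULT_SCREEN


@pytest.fixture(scope="session")
def design3() -> lm.TaskDesign:
    """The default 3-item, 100-trial task on the 1366x768 screen."""
    return lm.TaskDesign()


@pytest.fixture(scope="session")
def central_dataset(design3) -> lm.TrialDataset:
    """One dataset at the well-identified central cell (beta=gamma=.3, sigma=30)."""
    return lm.simulate_dataset(design3, 0.3, 0.3, 30.0, np.random.default_rng(12345))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
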