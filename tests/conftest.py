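import numpy as np
import pytest

import qlvfit as q

#: rates of the three-rate characterisation protocol [1/s]
RATES = (0.01, 150.0, 300.0)


@pytest.fixture(scope="session")
def presets():
    return q.material_presets()


@pytest.fixture(scope="session")
def designs():
    return q.design_presets()


@pytest.fixture(scope="session")
def cerebrum(presets):
    return presets["cerebrum"]


def noiseless_curves(material, mode, max_strain, n_steps=1000, rates=RATES):
    """True QLV curves of a material at the three protocol rates."""
    return [q.rate_response_curve(material, mode, r, max_strain, n_steps=n_steps)
            for r in rates]


@pytest.fixture(scope="session")
def small_fit_config():
    """Reduced-cost fit configuration for tests that exercise fitting
    machinery rather than recovery accuracy."""
    return q.FitConfig(n_starts=4, n_steps=300)
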