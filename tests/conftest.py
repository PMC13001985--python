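import numpy as np
import pytest

import bdlm


@pytest.fixture(scope="session")
def default_panel():
    return bdlm.generate_panel(seed=7)


@pytest.fixture(scope="session")
def default_design(default_panel):
    return bdlm.build_design(default_panel)


@pytest.fixture(scope="session")
def tiny_panel():
    """Two districts over 2014-2016 (spans several policy onsets)."""
    config = bdlm.SimulationConfig(
        n_districts=2,
        start=(2014, 1),
        end=(2016, 12),
        districts=(("Aru", "Northern"), ("Bugiri", "Eastern")),
    )
    return bdlm.generate_panel(config, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
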