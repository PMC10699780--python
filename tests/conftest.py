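import pytest

import reefres as rr


@pytest.fixture(scope="session")
def config():
    return rr.CalibrationConfig()


@pytest.fixture(scope="session")
def islands(config):
    return rr.generate_islands(config)


@pytest.fixture(scope="session")
def experimental_tables(islands, config):
    return rr.generate_colonies(islands, config, "experimental", seed=11)


@pytest.fixture(scope="session")
def natural_tables(islands, config):
    return rr.generate_colonies(islands, config, "natural", seed=11)
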