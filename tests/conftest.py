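import pytest
from hypothesis import settings

from matcea import default_config

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def config():
    """The shipped configuration with the published input table."""
    return default_config()


@pytest.fixture(scope="session")
def point_draw(config):
    """Point-estimate draw covering the primary scenarios."""
    return config.merged_params("soc", "kshi").point_draw()
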