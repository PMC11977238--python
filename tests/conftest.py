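import pytest
from hypothesis import settings

from dflashkit import SimConfig

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def clean_cfg():
    """Noise-free field config: interior nuclei only, exact rendering."""
    return SimConfig(border_fraction=0.0, cluster_fraction=0.0,
                     abnormal_fraction=0.0, noise_sd=0.0)


@pytest.fixture
def default_cfg():
    return SimConfig()
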