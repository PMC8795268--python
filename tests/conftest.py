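import pytest

from callihyb.cox2_haplotyping import ReferencePanel
from callihyb.synthetic_data import SimConfig, simulate_cohort, simulate_panel


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def default_panel(default_config) -> ReferencePanel:
    return simulate_panel(default_config)


@pytest.fixture(scope="session")
def noiseless_cohort(default_config, default_panel):
    cfg = SimConfig(seed=1, per_base_error=0.0, fragment_sigma=0.0)
    return simulate_cohort(cfg, default_panel)
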