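import numpy as np
import pytest

from sarcoscreen.simulate import GroupSpec, SimConfig, simulate_field


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def healthy_group():
    return GroupSpec(label="DMSO", is_control=True, healthy_fraction=1.0)


@pytest.fixture
def small_sarcomere_config():
    """Small 60x field (few cells) to keep unit tests fast."""
    return SimConfig(
        groups=[GroupSpec(label="DMSO", is_control=True, healthy_fraction=0.7)],
        rng_seed=11,
        field_shape=(300, 300),
        cells_per_field_mean=6,
    )


@pytest.fixture
def small_yap_config():
    return SimConfig(
        groups=[GroupSpec(label="DMSO", is_control=True, yap_nuclear_fraction=0.6)],
        rng_seed=12,
        mode="yap_4x",
        field_shape=(320, 320),
        cells_per_field_mean=60,
    )


@pytest.fixture
def sarcomere_field(small_sarcomere_config):
    cfg = small_sarcomere_config
    return simulate_field(cfg, cfg.groups[0], 0, 0, 1)


@pytest.fixture
def yap_field(small_yap_config):
    cfg = small_yap_config
    return simulate_field(cfg, cfg.groups[0], 0, 0, 1)
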