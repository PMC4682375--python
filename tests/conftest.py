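import pytest

from comirnet import SimulationConfig
from comirnet.synthetic import generate_study


def small_config(**overrides) -> SimulationConfig:
    """Fast desk-scale study: 3 platforms, 600 genes, 2 planted groups."""
    base = dict(
        n_genes=600,
        n_mirnas=30,
        n_datasets=3,
        samples_per_group=6,
        frac_up_de=0.1,
        frac_down_de=0.1,
        effect_size=4.0,
        noise_sd=0.5,
        platform_dropout=0.05,
        n_coop_groups=2,
        group_size=5,
        shared_pool_size=12,
        background_target_rate=0.03,
        seed=11,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_config())


@pytest.fixture(scope="session")
def default_study():
    """The full strong-signal study conditions (generator defaults)."""
    return generate_study(SimulationConfig(seed=7))
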