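import pytest

from lncmeth import SyntheticConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_samples=60, n_clusters=3, n_lncrna=80, n_pcg=30,
        n_assoc_lncrna=8, seed=3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)
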