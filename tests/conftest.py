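import pytest

from neomir.simulate import (
    SyntheticConfig,
    generate_reference,
    make_manifest,
    simulate_counts,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Desk-scale study: full 35-sample design, modest depth."""
    return SyntheticConfig(seed=11, n_mirnas=60, libsize_range=(3000, 5000))


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference(small_config)


@pytest.fixture(scope="session")
def small_manifest(small_config):
    return make_manifest(small_config)


@pytest.fixture(scope="session")
def small_counts(small_config, small_reference, small_manifest):
    return simulate_counts(
        small_config,
        small_reference.truth,
        small_manifest,
        [m.id for m in small_reference.matures],
    )
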