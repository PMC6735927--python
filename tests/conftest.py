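import pytest

from dupdiverge.synthetic import GeneratorConfig, generate_dataset


def tiny_config(**overrides) -> GeneratorConfig:
    base = dict(
        n_species=2,
        n_families=70,
        n_block_pairs=20,
        n_tandem_pairs=20,
        n_unclassified_pairs=5,
        n_conditions=40,
        seed=11,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small two-species dataset shared by read-only tests."""
    return generate_dataset(tiny_config())


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Single-species dataset with zero noise: realized stats equal latent
    curve values up to rounding, which the recovery tests rely on."""
    return generate_dataset(
        tiny_config(n_species=1, noise_sd=0.0, n_conditions=100, seed=5)
    )
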