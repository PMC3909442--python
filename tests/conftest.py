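import pytest

from famagg import SyntheticConfig, generate_cohort, load_table3, load_table4


@pytest.fixture(scope="session")
def table3():
    return load_table3()


@pytest.fixture(scope="session")
def table4():
    return load_table4()


@pytest.fixture(scope="session")
def small_cohort():
    """Well-separated cohort of 100 singleton samples, 5 subtypes."""
    config = SyntheticConfig(
        n_genes=100, n_markers_per_subtype=10, delta=2.0, sigma=0.5,
        family_sizes=(1,) * 100, seed=7,
    )
    return config, generate_cohort(config)
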