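import pytest
from hypothesis import HealthCheck, settings

from chemlandscape.io_curation import curate
from chemlandscape.synthetic_data import SynthConfig, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 8 families x 40 members, 30 duplicates,
    20 essential-value violations, 10 planted cliffs at delta pIC50 2.5."""
    return generate_dataset(SynthConfig())


@pytest.fixture(scope="session")
def default_truth(default_dataset):
    return default_dataset[1]


@pytest.fixture(scope="session")
def curated_default(default_dataset):
    curated, log = curate(default_dataset[0])
    return curated, log


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SynthConfig(
        members_per_family=10,
        n_duplicates=5,
        n_missing_value=3,
        n_noneq_relation=2,
        n_planted_cliffs=2,
        seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_curated(small_dataset):
    curated, log = curate(small_dataset[0])
    return curated, log
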