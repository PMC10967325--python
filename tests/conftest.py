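"""Shared fixtures: small synthetic benchmark datasets, generated at test time."""

import pytest

from enrspace import synthetic
from enrspace.curation import curate


@pytest.fixture(scope="session")
def small_spec():
    return synthetic.default_spec(
        seed=42,
        n_per_enzyme={"InhA": 120, "FabI": 60, "FabK": 25, "FabV": 15},
        noise_sd=0.3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return synthetic.generate_dataset(small_spec)


@pytest.fixture(scope="session")
def curated_small(small_dataset):
    records, _ = small_dataset
    curated, _ = curate(records)
    return curated


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Deterministic activities: used for ground-truth recovery checks."""
    spec = synthetic.default_spec(
        seed=7,
        noise_sd=0.0,
        qualitative_fraction=0.0,
        n_per_enzyme={"InhA": 200, "FabI": 100, "FabK": 30, "FabV": 15},
    )
    return synthetic.generate_dataset(spec)
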