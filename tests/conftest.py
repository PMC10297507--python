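"""Shared fixtures: packaged sample records and seeded synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from heartrisk import datagen, ioformats, preprocess


@pytest.fixture(scope="session")
def sample_records():
    """The packaged ten-row sample file, read leniently."""
    records, issues = ioformats.read_records(ioformats.sample_records_path())
    return records, issues


@pytest.fixture(scope="session")
def schema_enc():
    return preprocess.schema_encoder()


@pytest.fixture(scope="session")
def separable_cohort():
    """2000 records with a noise-free single-attribute label signal."""
    config = datagen.CohortConfig(n_records=2000, seed=42)
    return datagen.generate_cohort(config, datagen.separable_signal())


@pytest.fixture(scope="session")
def noisy_cohort():
    """500 records under the default multi-attribute logistic signal."""
    config = datagen.CohortConfig(n_records=500, seed=3)
    return datagen.generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
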