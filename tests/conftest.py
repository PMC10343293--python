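import numpy as np
import pytest

from pkunmr.classifier import ClassifierConfig, mccv
from pkunmr.spectral_binning import assemble_bucket_table
from pkunmr.synthetic_cohort import (
    CohortConfig,
    generate_concentrations,
    load_default_panel,
    synthesize_spectrum,
)


@pytest.fixture(scope="session")
def default_panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def default_cohort(default_panel):
    """36 case vs 51 control concentration table from the calibrated panel."""
    config = CohortConfig(n_case=36, n_control=51, panel=default_panel, seed=11)
    table, labels = generate_concentrations(config)
    return config, table, labels


@pytest.fixture(scope="session")
def default_buckets(default_panel, default_cohort):
    """Bucket table of synthesized spectra for the default cohort."""
    config, table, labels = default_cohort
    spectra = [
        synthesize_spectrum(table.iloc[i].fillna(0.0), default_panel,
                            noise_sd=config.noise_sd, seed=config.seed * 1000 + i)
        for i in range(len(table))
    ]
    return assemble_bucket_table(spectra, sample_ids=list(table.index)), labels


@pytest.fixture(scope="session")
def default_mccv(default_buckets):
    buckets, labels = default_buckets
    return mccv(buckets.matrix, labels.to_numpy(), ClassifierConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
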