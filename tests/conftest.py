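import numpy as np
import pytest

from gemtox import (
    CovariateVector,
    OTUCountTable,
    SyntheticDesign,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_design() -> SyntheticDesign:
    """Desk-scale design: quick to simulate, still structured like the
    full study (baseline zeros, ties, skewed abundances)."""
    return SyntheticDesign(n_sites=12, n_baseline=5, n_otus=60,
                           max_covariate=22_000.0, effect_scale=3.0,
                           depth_range=(1_000, 3_000), seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return simulate_dataset(small_design)


@pytest.fixture
def tiny_table() -> OTUCountTable:
    counts = np.array([[5, 0], [1, 2], [0, 7]])
    return OTUCountTable(counts=counts,
                         otu_ids=("otu_a", "otu_b", "otu_c"),
                         site_ids=("s1", "s2"),
                         genera=("genus_1", "genus_2", None))


@pytest.fixture
def tied_covariates() -> CovariateVector:
    return CovariateVector(raw=np.array([0.0, 0.0, 5000.0, 5000.0, 22000.0]),
                           site_ids=("s1", "s2", "s3", "s4", "s5"))
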