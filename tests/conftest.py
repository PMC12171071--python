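import pytest

from viticlaims.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    # small but fully featured population: decoys, gaps, comorbidities
    return GeneratorConfig(n_persons=4000, seed=11, treated_vitiligo_prevalence=0.01)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def clean_dataset():
    """No decoys, no coverage gaps: the case algorithm must recover truth
    exactly on this dataset."""
    cfg = GeneratorConfig(n_persons=4000, seed=23, treated_vitiligo_prevalence=0.012,
                          decoy_dx_rate=0.0, decoy_treatment_rate=0.0,
                          coverage_gap_rate=0.0)
    return generate_dataset(cfg)
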