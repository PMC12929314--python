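import pytest

from nmpcea.effectiveness import add_scores, toy_value_set
from nmpcea.params_io import ModelConfig
from nmpcea.synthetic_data import SynthDesign, generate_patients, make_paper_fixture


@pytest.fixture(scope="session")
def dietitian_fixture():
    return make_paper_fixture("dietitian")


@pytest.fixture(scope="session")
def tr_fixture():
    return make_paper_fixture("therapeutic_radiographer")


@pytest.fixture(scope="session")
def value_set():
    return toy_value_set()


@pytest.fixture(scope="session")
def scored_patients():
    """Mid-sized synthetic cohort with a known utility effect of -0.05."""
    design = SynthDesign(
        patients_per_site=13, group_utility_effect=-0.05, site_random_sd=0.02,
        seed=42,
    )
    return add_scores(generate_patients(design))


@pytest.fixture
def base_config():
    return ModelConfig()
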