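import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cqival.survey_model import default_item_map
from cqival.synthetic import GeneratorConfig, generate

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def item_map():
    return default_item_map()


@pytest.fixture(scope="session")
def small_survey():
    """A small complete survey: 6 hospitals x 4 departments x ~30 respondents."""
    cfg = GeneratorConfig(
        n_hospitals=6,
        departments_per_hospital=4,
        respondents_per_department=(20, 40),
        seed=101,
    )
    ds, truth = generate(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def medium_survey():
    """A mid-sized complete survey used by CFA and reliability tests."""
    cfg = GeneratorConfig(
        n_hospitals=10,
        departments_per_hospital=5,
        respondents_per_department=100,
        seed=202,
    )
    ds, truth = generate(cfg)
    return ds, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
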