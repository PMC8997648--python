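import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ferment_screen as fs

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design243() -> fs.DesignTable:
    """Default 7-factor 3^(7-2) screening design."""
    return fs.build_design()


@pytest.fixture(scope="session")
def pipeline_records(design243):
    """Simulated responses for every run of the default design."""
    return fs.run_design(design243)


@pytest.fixture(scope="session")
def mu_fit(design243, pipeline_records):
    """Reduced second-order fit of mu_max on the default pipeline output."""
    frame = fs.responses_to_frame(pipeline_records)
    mm = fs.build_model_matrix(design243)
    fit = fs.fit_quadratic(mm, frame["mu_max"].to_numpy(), "mu_max",
                           codes=design243.codes)
    return fs.backward_eliminate(fit)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20220325)
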