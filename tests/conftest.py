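import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenario1_dataset():
    """A moderate scenario-1 dataset with confounding (beta=0.5, gamma=1)."""
    from ordcausal import SimulationDesign, simulate_dataset

    return simulate_dataset(
        SimulationDesign(scenario=1, n=2000, beta=0.5, gamma=1.0, seed=424242)
    )


@pytest.fixture(scope="session")
def tiny_survey():
    """A small synthetic survey for pipeline plumbing tests."""
    from ordcausal import SurveyDesign, generate_survey

    return generate_survey(SurveyDesign(n=400, seed=99))


def assert_close(a, b, tol, msg=""):
    assert abs(a - b) <= tol, f"{msg}: |{a} - {b}| > {tol}"
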