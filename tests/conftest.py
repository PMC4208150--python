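import pytest
from hypothesis import HealthCheck, settings

from promptlab import runner, synth_streams as ss

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def task1_script():
    return ss.make_task1_script()


@pytest.fixture(scope="session")
def task2_script():
    return ss.make_task2_script((60.0,) * 10)


@pytest.fixture(scope="session")
def default_model():
    return ss.SignalModel.default()


@pytest.fixture(scope="session")
def task1_stream(task1_script, default_model):
    return ss.synthesize_stream(task1_script, default_model, seed=11)


@pytest.fixture(scope="session")
def trained_classifier(default_model):
    """Mixture classifier fitted on scripted synthetic streams (shared: slow)."""
    return runner._train_default_classifier(default_model, k=2, seed=0)
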