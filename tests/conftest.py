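import pytest
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
def toy_annotation():
    from splicedx.simulate import make_toy_annotation

    return make_toy_annotation(0)


@pytest.fixture(scope="session")
def models(toy_annotation):
    return toy_annotation.models


@pytest.fixture(scope="session")
def tx_seqs(toy_annotation):
    return toy_annotation.transcript_sequences()
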