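import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    from forageweb import default_parameters
    return default_parameters()


@pytest.fixture(scope="session")
def nofish_200(params):
    """Unfished 200-yr run at the constant-forcing calibration."""
    from forageweb import simulate, PolicyPath
    return simulate(params, PolicyPath.moratorium(), T=200, dt=0.05)
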