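import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tmm_compositions():
    from phantomrad import reference_data

    return {c.material_name: c for c in reference_data.load_compositions("tmm")}


@pytest.fixture(scope="session")
def icru_compositions():
    from phantomrad import reference_data

    return {c.material_name: c for c in reference_data.load_compositions("icru")}


@pytest.fixture(scope="session")
def mac_table():
    from phantomrad import default_attenuation_table

    return default_attenuation_table()
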