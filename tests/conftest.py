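import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cgh_cohort():
    """Default chromosome-3 cohort: (profiles, truth, clone_map)."""
    from ampliconmap import synthetic_data as sd

    return sd.make_cgh_cohort()


@pytest.fixture(scope="session")
def tiling_cohort():
    from ampliconmap import synthetic_data as sd

    return sd.make_tiling_cohort()


@pytest.fixture(scope="session")
def expression_dataset():
    from ampliconmap import synthetic_data as sd

    return sd.make_expression_dataset()


@pytest.fixture(scope="session")
def qpcr_fixture():
    from ampliconmap import synthetic_data as sd

    return sd.make_qpcr_fixture()


@pytest.fixture(scope="session")
def ihc_fixture():
    from ampliconmap import synthetic_data as sd

    return sd.make_ihc_fixture()
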