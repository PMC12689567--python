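import pytest

from pmckit import default_grade_scale, default_schema, load_mqimp_fixture


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def scale():
    return default_grade_scale()


@pytest.fixture(scope="session")
def study():
    """The packaged MQIMP evaluation marginals (22 policies, 9x3 system)."""
    return load_mqimp_fixture()
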