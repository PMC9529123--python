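import pytest

from acmghl.synthetic import make_fixture_set


@pytest.fixture(scope="session")
def fixture_set():
    """Default deterministic fixture set shared across the suite."""
    return make_fixture_set(seed=7)


@pytest.fixture(scope="session")
def bundle(fixture_set):
    return fixture_set.bundle()


@pytest.fixture(scope="session")
def fixture_dir(fixture_set, tmp_path_factory):
    """Fixture set written to disk; returns the directory path."""
    out = tmp_path_factory.mktemp("fixtures")
    fixture_set.write(out)
    return out
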