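import pytest

from cdr3kit.germline import GermlineIndex
from cdr3kit.simulate import synthetic_germline, write_germline_dir


@pytest.fixture(scope="session")
def fixture_segments():
    return synthetic_germline(0)


@pytest.fixture(scope="session")
def fixture_index(fixture_segments):
    return GermlineIndex.build(fixture_segments)


@pytest.fixture(scope="session")
def igh_index(fixture_segments):
    return GermlineIndex.build([s for s in fixture_segments if s.chain == "IGH"])


@pytest.fixture()
def germline_dir(tmp_path, fixture_segments):
    path = tmp_path / "germline"
    write_germline_dir(fixture_segments, str(path))
    return str(path)
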