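import json
from pathlib import Path

import pytest

from protoscheme.classify import default_vocabulary
from protoscheme.fixtures import generate_fixtures


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> Path:
    """One generated synthetic fixture tree shared by the whole session."""
    out = tmp_path_factory.mktemp("fixtures")
    generate_fixtures(seed=7, out_dir=out)
    return out


@pytest.fixture(scope="session")
def manifest(fixture_dir) -> dict:
    return json.loads((fixture_dir / "manifest.json").read_text())


@pytest.fixture(scope="session")
def cd45_dir() -> Path:
    """Directory holding the packaged CD45 stand-in records."""
    from importlib import resources

    return Path(str(resources.files("protoscheme.data")))
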