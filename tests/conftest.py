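from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")

REPO_ROOT = Path(__file__).resolve().parent.parent


@pytest.fixture(scope="session")
def appendix_fixture_path() -> Path:
    return REPO_ROOT / "examples" / "fixtures" / "appendix_granularity.csv"
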