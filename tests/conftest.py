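from pathlib import Path

import pytest

from seqcheck.fixtures import FixtureSpec, make_fixture


@pytest.fixture
def forge(tmp_path):
    """Build a fixture file in this test's tmp dir from keyword arguments."""

    def _make(fmt: str, **kwargs) -> Path:
        return make_fixture(FixtureSpec(fmt, **kwargs), tmp_path)

    return _make
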