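import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

from piezocomp import load_da_fixture, load_table1_fixture  # noqa: E402


@pytest.fixture(scope="session")
def table1():
    """Packaged 20x20 directed substitution count table."""
    return load_table1_fixture()


@pytest.fixture(scope="session")
def da_table():
    """Packaged differential-abundance spot lists."""
    return load_da_fixture()
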