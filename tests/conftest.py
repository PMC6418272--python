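import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mromgla import Lexicon, micro_fixture


@pytest.fixture
def toy_lexicon() -> Lexicon:
    """Four short words with known neighborhood/bigram structure."""
    return Lexicon.from_entries(
        [("cat", 10.0), ("cot", 5.0), ("cog", 3.0), ("dog", 7.0)]
    )


@pytest.fixture(scope="session")
def micro():
    """Fixed 8-word lexicon, 4 stimuli, frozen parameters."""
    return micro_fixture()


@pytest.fixture(scope="session")
def golden_gla() -> dict:
    import json

    path = Path(__file__).parent / "data" / "micro_golden.json"
    return json.loads(path.read_text())
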