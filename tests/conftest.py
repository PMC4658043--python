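import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mapkkk import load_drought_panel


@pytest.fixture(scope="session")
def drought_panel():
    """Bundled qRT-PCR panel: (lines x genes expression, lines x DTI)."""
    return load_drought_panel()
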