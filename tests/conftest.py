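import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from pairsurv.simulate import make_worked_fixture


@pytest.fixture(scope="session")
def worked():
    """The deterministic 12-sample, 8-gene micro-cohort."""
    return make_worked_fixture()
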