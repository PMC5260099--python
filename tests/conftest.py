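import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from _utils import linear_chain  # noqa: E402

from mut3d.structure_io import compute_contact_map  # noqa: E402


@pytest.fixture
def chain6():
    """Six CA-only residues on a line, 3.8 A apart (contacts i, i+1)."""
    return linear_chain(6, spacing=3.8)


@pytest.fixture
def cmap6(chain6):
    return compute_contact_map(chain6)
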