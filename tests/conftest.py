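import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from pksurvey import synth


@pytest.fixture(scope="session")
def small_refdb():
    """Compact labeled reference: 3 lineage seeds per leaf class (33 entries)."""
    return synth.synthetic_reference(seed=11, lineages_per_leaf=3)


@pytest.fixture(scope="session")
def refdb_by_leaf(small_refdb):
    return synth.reference_by_leaf(small_refdb)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
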