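import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from tmetrace.treeio import read_newick


@pytest.fixture
def balanced4():
    """((A,B),(C,D)) with unit branch lengths."""
    return read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def chain3():
    """((A,B),C) caterpillar with unit branch lengths."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
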