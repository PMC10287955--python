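import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from aretools import MotifCatalog, normalize_sequence


@pytest.fixture
def catalog():
    return MotifCatalog.default()


@pytest.fixture
def rng():
    return np.random.default_rng(20260906)


def random_rna(rng, length, alphabet="ACGU"):
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture
def make_seq():
    def _make(residues, id="s"):
        return normalize_sequence(residues, "rna", id=id)

    return _make
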