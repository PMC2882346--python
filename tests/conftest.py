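import io

import pytest

from parablade import load_blosum62
from parablade.seqio import read_structure
from parablade.synthetic_data import make_toy_structure


@pytest.fixture(scope="session")
def blosum62():
    return load_blosum62()


@pytest.fixture(scope="session")
def toy_structure():
    """7 blades x 10 residues starting at 301, fully resolved."""
    pdb_text, annotation = make_toy_structure(7, 10, 301)
    structure = read_structure(io.StringIO(pdb_text), chain="A",
                               seq_span=(301, 370), source="toy")
    return structure, annotation


@pytest.fixture(scope="session")
def two_blade_structure():
    """2 blades x 3 residues starting at 1 (tiny exhaustive-null case)."""
    pdb_text, annotation = make_toy_structure(2, 3, 1)
    structure = read_structure(io.StringIO(pdb_text), chain="A",
                               seq_span=(1, 6), source="toy2")
    return structure, annotation
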