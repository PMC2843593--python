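import random

import pytest

from lanthirings import presets
from lanthirings.peptide import ModifiedPeptide

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def venezuelin_core():
    """The modified GluC core fragment (Thr18-Ala51) of the preset."""
    return presets.venezuelin_core()


@pytest.fixture
def venezuelin_observations():
    return presets.venezuelin_observations()


def random_peptide(rng: random.Random, length: int, ident: str = "p") -> ModifiedPeptide:
    seq = "".join(rng.choice(AMINO_ACIDS) for _ in range(length))
    return ModifiedPeptide(id=ident, sequence=seq)


@pytest.fixture
def rng():
    return random.Random(20260918)
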