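import numpy as np
import pytest

from orthounmask.seqio import Alignment, SequenceRecord
from orthounmask.synthetic_data import stepping_stone_scenario


@pytest.fixture()
def motif_alignment():
    """Five near-identical copies of a short anchored motif."""
    return Alignment([
        ("s1", "KYEIDV"),
        ("s2", "KYEIDV"),
        ("s3", "KYELDV"),
        ("s4", "KYEIDV"),
        ("s5", "KYEIDI"),
    ])


@pytest.fixture()
def random_protein():
    rng = np.random.default_rng(42)
    from orthounmask.seqio import AMINO_ACIDS
    return SequenceRecord(
        "rand", "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 80)))


@pytest.fixture(scope="session")
def stepping_stone():
    """The calibrated stepping-stone dataset shared across tests."""
    return stepping_stone_scenario(seed=11)
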