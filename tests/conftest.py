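import numpy as np
import pytest

from rdhfp.seqalign import Molecule, SequenceRecord, SequenceSet


@pytest.fixture
def aa_records():
    return SequenceSet(
        [
            SequenceRecord("a", Molecule.AA, "MKVLITG"),
            SequenceRecord("b", Molecule.AA, "MKVLITG"),
            SequenceRecord("c", Molecule.AA, "WWPHHHY"),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


def random_nt(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def random_aa(rng, length):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
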