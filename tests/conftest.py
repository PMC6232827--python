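import numpy as np
import pytest

import cleavescan as cs
from cleavescan.core import AlignedPeptide, AlignedPeptideBlock


@pytest.fixture(scope="session")
def scheme():
    return cs.DEFAULT_CLASS_SCHEME


@pytest.fixture(scope="session")
def hne_truth():
    """Default hNE ground truth used by the simulator."""
    return cs.GroundTruthModel(pwm=cs.truth_matrix("hNE"))


@pytest.fixture
def simple_block():
    """Four centered nonamers, Val/Ile at P1, Ser at P1'."""
    return AlignedPeptideBlock(
        [
            AlignedPeptide("GLLAVSGRE", 1, 0),
            AlignedPeptide("ALVLVSEKG", 1, 0),
            AlignedPeptide("KIVAISDLG", 2, 0),
            AlignedPeptide("GGLPVSRAA", 1, 0),
        ],
        mode="mask",
    )


def random_block(rng, n_peptides=6, mode="mask"):
    """A random centered block (helper, not a fixture)."""
    seqs = [
        "".join(rng.choice(list(cs.AMINO_ACIDS), size=9))
        for _ in range(n_peptides)
    ]
    counts = rng.integers(1, 4, size=n_peptides)
    return AlignedPeptideBlock(
        [AlignedPeptide(s, int(c), 0) for s, c in zip(seqs, counts)],
        mode=mode,
    )
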