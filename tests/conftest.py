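"""Shared fixtures.

The mature miR-199a-5p sequence is the miRBase constant; the two construct
sequences are the printed wild-type and seed-mutant CAV1 3'UTR fragments
used as the worked example for site scanning.
"""

import numpy as np
import pytest

from mirseed.formats import MatureMirna, SequenceSet

MIR199A_5P = "CCCAGUGUUCAGACUACCUGUUC"

CAV1_WT_SENSE = (
    "TCGAGGACACTTTAATTACCAACCTGTTACCTACTTTGACTTTTTGCATTTAAAACAGACACTGGC"
    "ATGGATATAGTTTTACTTTTAAACTGTGTACGC"
)
CAV1_MUT_SENSE = (
    "TCGAGGACACTTTAATTACCAACCTGTTACCTACTTTGACTTTTTGCATTTAAAACAGAGAGTCGC"
    "ATGGATATAGTTTTACTTTTAAACTGTGTACGC"
)


@pytest.fixture
def mir199():
    return MatureMirna("hsa-miR-199a-5p", MIR199A_5P)


@pytest.fixture
def cav1_constructs():
    ss = SequenceSet()
    ss.add("wt", CAV1_WT_SENSE)
    ss.add("mut", CAV1_MUT_SENSE)
    return ss


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
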