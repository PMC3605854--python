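import numpy as np
import pytest

from coalisle.containers import SequenceAlignment, STRDataset, DatasetBundle


def aln_from_strings(seqs, pops=None, names=None):
    names = names or [f"s{i}" for i in range(len(seqs))]
    pops = pops or [""] * len(seqs)
    return SequenceAlignment.from_strings(list(zip(names, seqs)), pops)


@pytest.fixture
def toy_alignment():
    # {AAAA, AAAT, AATT}: pair diffs 1, 2, 1
    return aln_from_strings(["AAAA", "AAAT", "AATT"])


@pytest.fixture
def toy_str_dataset():
    mat = np.array(
        [
            [10, 10],
            [10, 12],
            [12, 14],
            [12, 16],
            [12, 19],
            [12, 10],
            [12, 12],
            [12, 12],
        ]
    )
    pops = ["p1"] * 5 + ["p2"] * 3
    names = [f"c{i}" for i in range(8)]
    return STRDataset(names, pops, mat)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
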