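import numpy as np
import pytest

from enzdesign.conservation import Alignment


@pytest.fixture
def toy_alignment() -> Alignment:
    """5 rows x 3 columns used by the hand-computed PSSM oracle."""
    rows = ["AAC", "AAC", "ACC", "AGD", "A-C"]
    return Alignment(ids=[f"r{i}" for i in range(5)], rows=rows)


@pytest.fixture
def base_seq() -> str:
    """500-residue reference with the residues the worked examples expect."""
    seq = list("A" * 500)
    for pos, res in {
        46: "I", 48: "L", 49: "S", 61: "I", 73: "K", 89: "F", 109: "L",
        113: "F", 119: "W", 120: "L", 125: "L", 286: "E", 343: "C",
        352: "T", 356: "L", 383: "R", 385: "R", 399: "W", 432: "Y",
        439: "I", 463: "E",
    }.items():
        seq[pos - 1] = res
    return "".join(seq)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
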