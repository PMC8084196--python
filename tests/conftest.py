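import numpy as np
import pytest

from crisprflp import RestrictionEnzyme, default_catalog

# Independent IUPAC table for brute-force oracles (kept separate from the
# package's own table on purpose).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def brute_force_hits(seq: str, enzyme: RestrictionEnzyme):
    """Oracle: test every offset on both strands positionally."""
    m = enzyme.motif
    hits = []
    palindromic = m == revcomp(m)
    for s in range(len(seq) - len(m) + 1):
        window = seq[s : s + len(m)]
        if all(b in IUPAC[c] for c, b in zip(m, window)):
            hits.append((enzyme.name, s, s + len(m), "+"))
        if not palindromic and all(
            b in IUPAC[c] for c, b in zip(m, revcomp(window))
        ):
            hits.append((enzyme.name, s, s + len(m), "-"))
    return sorted(hits)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
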