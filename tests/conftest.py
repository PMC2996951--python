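import numpy as np
import pytest

from trna_anchor.iupac import bases
from trna_anchor.records import GeneFeature, MitoGenome
from trna_anchor.simulate import SimConfig, generate_corpus


def expand_uniform(consensus: str, rng: np.random.Generator) -> str:
    """One concrete expansion of a degenerate string, uniform per position."""
    return "".join(sorted(bases(c))[rng.integers(len(bases(c)))] for c in consensus)


def random_iupac(rng: np.random.Generator, length: int, max_degeneracy: int = 256) -> str:
    """A random IUPAC string built under a degeneracy budget."""
    codes = "ACGTMRWSYKVHDBN"
    out, d = [], 1
    for _ in range(length):
        allowed = [c for c in codes if d * len(bases(c)) <= max_degeneracy]
        c = allowed[rng.integers(len(allowed))]
        out.append(c)
        d *= len(bases(c))
    return "".join(out)


@pytest.fixture(scope="session")
def survey_corpus():
    """The default study-condition corpus: 126 genomes, 120 anchored, 92/28."""
    return generate_corpus(SimConfig(seed=20260925 % 2**31))


@pytest.fixture
def simple_genome():
    """trnW(+), trnC(-), trnY(-) directly upstream of COI(+)."""
    seq = "A" * 400
    feats = [
        GeneFeature("trnW", 40, 104, 1),
        GeneFeature("trnC", 110, 174, -1),
        GeneFeature("trnY", 180, 244, -1),
        GeneFeature("COI", 250, 370, 1),
    ]
    return MitoGenome("g1", seq, True, feats)
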