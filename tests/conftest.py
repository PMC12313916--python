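import numpy as np
import pytest

from stopswitch import q81x_mutant_cds, wt_egfp_cds


@pytest.fixture(scope="session")
def wt_cds():
    return wt_egfp_cds()


@pytest.fixture(scope="session")
def mutant_cds():
    return q81x_mutant_cds()


_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """A random ORF: ATG start, random sense codons, single terminal stop."""
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    stop = rng.choice(["TAA", "TAG", "TGA"])
    return "ATG" + "".join(body) + stop
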