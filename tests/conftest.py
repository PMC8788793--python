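import numpy as np
import pytest

from pletype.refdata import load_family_table, load_peptides, load_producers


@pytest.fixture(scope="session")
def families():
    return load_family_table()


@pytest.fixture(scope="session")
def producers(families):
    return load_producers(families=families)


@pytest.fixture(scope="session")
def peptides(families):
    return load_peptides(families=families)


@pytest.fixture(scope="session")
def peptide_by_name(peptides):
    def get(name, producer_substring=None):
        hits = [p for p in peptides if p.lp_name == name]
        if producer_substring:
            hits = [p for p in hits if producer_substring in p.producer]
        assert hits, f"no packaged peptide named {name!r}"
        return hits[0]

    return get


def random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
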