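import numpy as np
import pytest
from hypothesis import settings

from trflp.digest import builtin_enzymes
from trflp.fixtures import generate_fixture
from trflp.iupac import builtin_primers
from trflp.refdb import build_subset

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def enzymes():
    return builtin_enzymes()


@pytest.fixture(scope="session")
def primer_27f():
    return builtin_primers()["27F"]


@pytest.fixture(scope="session")
def small_bundle():
    """A small clean fixture shared by several tests (20 refs, 12 samples)."""
    return generate_fixture(11, n_refs=20, n_samples=12)


@pytest.fixture(scope="session")
def small_subset(small_bundle):
    return build_subset(small_bundle.references, small_bundle.primer)
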