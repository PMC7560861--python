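import numpy as np
import pytest

from mirhom.fold import StackingBackend, ViennaBackend
from mirhom.seqio import ReferenceMature


@pytest.fixture(scope="session")
def vienna():
    return ViennaBackend()


@pytest.fixture(scope="session")
def stacking():
    return StackingBackend()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def random_seq(rng, n, gc=0.5):
    bases = np.array(list("ACGT"))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(bases, size=n, p=p))


@pytest.fixture()
def small_refs(rng):
    """Ten random 21-nt references with exact 50% GC."""
    from mirhom.synth import make_reference_set

    return make_reference_set(rng, n_refs=10, length=21)


def make_ref(seq, rid="ref-miR9999"):
    return ReferenceMature(id=rid, seq=seq)
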