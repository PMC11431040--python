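import numpy as np
import pytest

from mprtseq.construct import MrnaConstruct, RtPrimer
from mprtseq.synthetic_reference import reference_bundle


@pytest.fixture(scope="session")
def bundle():
    """Bundled deterministic reference construct/structure/profiles."""
    return reference_bundle()


@pytest.fixture(scope="session")
def small_construct():
    """A 500-nt single-primer construct for round-trip arithmetic tests."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGU"), size=500))
    return MrnaConstruct(
        name="mini",
        sequence=seq,
        elements=[("body", 1, 500)],
        primers=[RtPrimer("P1", 480, 499)],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
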