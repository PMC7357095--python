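import numpy as np
import pytest

from gesrev.signatures import EntityKind, GeneSignature, build_signature
from gesrev.simulate import make_fixture_bundle


def make_sig(sig_id, up, down, *, kind="drug", name=None, organism="human", series=""):
    """Shorthand signature constructor for tests."""
    return build_signature(
        signature_id=sig_id,
        entity_kind=kind,
        entity_name=name or sig_id,
        organism=organism,
        up=up,
        down=down,
        series_id=series,
    )


def random_signature(rng, sig_id, universe, *, kind="drug", name=None):
    """A random signature over ``universe`` with disjoint non-empty up/down."""
    n = int(rng.integers(2, max(3, len(universe) // 2)))
    chosen = rng.choice(np.asarray(universe), size=n, replace=False)
    split = int(rng.integers(1, n)) if n > 1 else 1
    return make_sig(sig_id, chosen[:split], chosen[split:], kind=kind, name=name)


@pytest.fixture(scope="session")
def fixture_study():
    return make_fixture_bundle()


@pytest.fixture
def rng():
    return np.random.default_rng(20200616)
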