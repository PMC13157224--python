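import numpy as np
import pytest

from fedcrypt.he.engine import HEParams, ReferenceBackend, mp_keygen
from fedcrypt.mpc.engine import MpcSession
from fedcrypt.mpc.ring import RingParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def mpc_session():
    """Default-parameter session (k=64, f=16, two parties)."""
    return MpcSession(RingParams(), seed=101)


@pytest.fixture
def wide_session():
    """Protocol-grade session with extra headroom."""
    return MpcSession(RingParams(k=192, f=40), seed=202)


@pytest.fixture
def small_he():
    """Tiny HE context (8 slots) for slot-level semantics tests."""
    params = HEParams(ring_dim=16, n_parties=2)
    backend = ReferenceBackend(params, seed=7)
    keys = mp_keygen(params, ["a", "b"], seed=7)
    return params, backend, keys


@pytest.fixture
def he_ctx():
    """Full-size HE context (16384 slots)."""
    params = HEParams(n_parties=2)
    backend = ReferenceBackend(params, seed=11)
    keys = mp_keygen(params, ["genomic", "phenotype"], seed=11)
    return params, backend, keys
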