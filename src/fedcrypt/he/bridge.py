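"""HE <-> MPC conversion.

he2mpc: the parties isolate one slot (plaintext one-hot multiply), each
homomorphically adds a private uniform mask, and collaboratively decrypt;
only the masked sum ever appears. Each party's negated mask becomes its
additive share; the opening party folds the decrypted value into its share.

mpc2he: the parties open a masked reconstruction (each adds a private mask
to its own share), the masked value is re-encrypted under the joint key and
the masks are homomorphically removed.

Masks are uniform over [0, 2^20 * value_bound): wide enough to hide the
value statistically at the reference backend's float64 slot precision. A
lattice backend, with exact big-integer plaintext space, would widen this
to 2^stat_sec * value_bound.
"""

from __future__ import annotations

import numpy as np

from fedcrypt.he.engine import (
    CipherVector,
    KeyShareSet,
    ReferenceBackend,
    collab_decrypt,
    h_add,
    h_mul,
)
from fedcrypt.mpc.engine import MpcSession, SecretShare
from fedcrypt.mpc.ring import decode

__all__ = ["he2mpc", "mpc2he", "MASK_BITS"]

MASK_BITS = 20


def _mask_range_int(session: MpcSession, value_bound: float) -> int:
    # masks are ring integers (scale 2^f); range = 2^MASK_BITS * bound
    return max(1, int(value_bound)) << (MASK_BITS + session.params.f)


def he2mpc(
    ct: CipherVector,
    slot: int,
    keys: KeyShareSet,
    backend: ReferenceBackend,
    session: MpcSession,
    value_bound: float,
) -> SecretShare:
    """Convert one ciphertext slot into an additive sharing."""
    if not (0 <= slot < ct.n_slots_used):
        raise IndexError(f"slot {slot} outside used range {ct.n_slots_used}")
    n = session.params.n_parties
    rng = session._input_rng
    rint = _mask_range_int(session, value_bound)
    mask_ints = [rng.randrange(rint) for _ in range(n)]

    onehot = np.zeros(ct.n_slots_used)
    onehot[slot] = 1.0
    masked_ct = h_mul(ct, onehot)
    # Masks ride in extended precision: a lattice scheme adds them in its
    # exact big-integer plaintext space, so the float64 slot width must not
    # clip the value's low bits under a large mask.
    scale_ld = np.longdouble(session.params.scale)
    for m in mask_ints:
        vec = np.zeros(ct.n_slots_used, dtype=np.longdouble)
        vec[slot] = np.longdouble(m) / scale_ld
        masked_ct = h_add(masked_ct, vec)

    opened = collab_decrypt(masked_ct, keys, backend)[slot]
    session.transcript.log("open", "he2mpc:masked", float(opened))

    mod = session.params.modulus
    shares = [(-m) % mod for m in mask_ints]
    opened_ring = int(np.rint(np.longdouble(opened) * scale_ld))
    shares[0] = (shares[0] + opened_ring) % mod
    return SecretShare(shares, session)


def mpc2he(
    x: SecretShare,
    keys: KeyShareSet,
    backend: ReferenceBackend,
    value_bound: float,
) -> CipherVector:
    """Convert an additive sharing into a (single-slot) ciphertext."""
    session = x.session
    n = session.params.n_parties
    rng = session._input_rng
    rint = _mask_range_int(session, value_bound)
    mask_ints = [rng.randrange(rint) for _ in range(n)]

    masked = SecretShare(
        [s + m for s, m in zip(x.shares, mask_ints)], session
    )
    opened = decode(session.open(masked, "mpc2he:masked"), session.params)

    ct = backend.encrypt([opened], keys)
    for m in mask_ints:
        ct = h_add(ct, [-m / session.params.scale])
    return ct
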