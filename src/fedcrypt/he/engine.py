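"""Multiparty HE engine: keys, ciphertexts, slot-wise arithmetic.

Default parameters mirror a 128-bit-secure CKKS instantiation: ring
dimension 32768 (16384 SIMD slots), 40-bit scale, depth budget 6
(logQ = 730 at scale 40). The joint private key is additively split: every
party contributes a share at keygen and every party must contribute a
partial decryption; no single party's material decrypts anything.
"""

from __future__ import annotations

import hashlib
import secrets
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HEParams",
    "CipherVector",
    "EncryptedVector",
    "KeyShareSet",
    "ReferenceBackend",
    "PackingError",
    "DepthError",
    "KeyMismatchError",
    "DecryptionError",
    "mp_keygen",
    "h_encrypt",
    "collab_decrypt",
    "h_add",
    "h_mul",
    "h_rotate",
    "h_total_sum",
    "h_masked_inner",
]


class PackingError(ValueError):
    """Vector longer than the slot count (caller must chunk)."""


class DepthError(RuntimeError):
    """Multiplicative depth budget exhausted (no bootstrapping in scope)."""


class KeyMismatchError(RuntimeError):
    """Operation between ciphertexts under different joint keys."""


class DecryptionError(RuntimeError):
    """Collaborative decryption attempted without all parties."""


@dataclass(frozen=True)
class HEParams:
    ring_dim: int = 32768
    scale_bits: int = 40
    security_bits: int = 128
    n_parties: int = 2
    depth_budget: int = 6

    def __post_init__(self) -> None:
        if self.ring_dim & (self.ring_dim - 1) or self.ring_dim < 4:
            raise ValueError("ring_dim must be a power of two >= 4")
        if self.n_parties < 1:
            raise ValueError("need >= 1 party")

    @property
    def slot_count(self) -> int:
        return self.ring_dim // 2


@dataclass(frozen=True)
class PrivateKeyShare:
    party: str
    secret: bytes


@dataclass(frozen=True)
class PartialDecryption:
    party: str
    ct_nonce: str
    proof: str


@dataclass(frozen=True)
class KeyShareSet:
    """Joint public key material plus per-party private shares.

    The joint key fingerprint commits to every party's share; decryption
    verifies one valid partial per party against those commitments.
    """

    parties: tuple[str, ...]
    key_id: str
    commitments: dict[str, str]
    _shares: dict[str, PrivateKeyShare] = field(repr=False, default_factory=dict)

    def share_for(self, party: str) -> PrivateKeyShare:
        return self._shares[party]


def mp_keygen(params: HEParams, parties, seed: int | None = None) -> KeyShareSet:
    """Collaborative keygen: each party samples its private-key share; the
    joint public key commits to all of them."""
    parties = tuple(str(p) for p in parties)
    if len(parties) != params.n_parties:
        raise KeyMismatchError(
            f"params declare {params.n_parties} parties, got {len(parties)}"
        )
    shares = {}
    for i, p in enumerate(parties):
        if seed is None:
            secret = secrets.token_bytes(32)
        else:
            secret = hashlib.sha256(f"keyshare:{seed}:{i}:{p}".encode()).digest()
        shares[p] = PrivateKeyShare(p, secret)
    commitments = {
        p: hashlib.sha256(b"commit:" + s.secret).hexdigest() for p, s in shares.items()
    }
    key_id = hashlib.sha256(
        ("|".join(commitments[p] for p in parties)).encode()
    ).hexdigest()[:32]
    return KeyShareSet(parties, key_id, commitments, shares)


class CipherVector:
    """One SIMD ciphertext: opaque encrypted slots, depth level, key id.

    Slots are deliberately unreachable from outside the backend: the only
    way to observe plaintext is ``collab_decrypt`` with a valid partial
    decryption from every party.
    """

    __slots__ = ("__payload", "n_slots_used", "level", "key_id", "nonce", "backend")

    def __init__(self, payload, n_slots_used, level, key_id, nonce, backend):
        self.__payload = payload
        self.n_slots_used = n_slots_used
        self.level = level
        self.key_id = key_id
        self.nonce = nonce
        self.backend = backend

    def _payload_for(self, backend: "ReferenceBackend"):
        if backend is not self.backend:
            raise KeyMismatchError("foreign backend cannot touch this ciphertext")
        return self.__payload


class ReferenceBackend:
    """Cleartext-slot backend enforcing the ciphertext contract.

    Injects seeded Gaussian relative noise of magnitude 2^-scale_bits per
    homomorphic operation, tracks multiplicative depth, and refuses slot
    access outside collaborative decryption.
    """

    name = "reference"

    def __init__(self, params: HEParams, seed: int = 0) -> None:
        self.params = params
        self._rng = np.random.default_rng(
            int.from_bytes(hashlib.sha256(f"henoise:{seed}".encode()).digest()[:8], "big")
        )
        self._ct_counter = 0

    # ------------------------------------------------------------------ noise
    def _noisy(self, slots: np.ndarray) -> np.ndarray:
        # Additive Gaussian noise at 2^-scale_bits absolute, emulating a
        # scale-managed approximate scheme whose error floor is set by the
        # rescaling precision, not by slot magnitude.
        eps = self._rng.normal(0.0, 2.0 ** -self.params.scale_bits, slots.shape)
        return slots + eps

    def _fresh(self, slots, n_used, level, keys: KeyShareSet) -> CipherVector:
        self._ct_counter += 1
        nonce = f"ct{self._ct_counter}"
        return CipherVector(slots, n_used, level, keys.key_id, nonce, self)

    def _derived(self, ref: CipherVector, slots, n_used=None, level=None) -> CipherVector:
        self._ct_counter += 1
        return CipherVector(
            slots,
            ref.n_slots_used if n_used is None else n_used,
            ref.level if level is None else level,
            ref.key_id,
            f"ct{self._ct_counter}",
            self,
        )

    # -------------------------------------------------------------- transport
    def encrypt(self, vec, keys: KeyShareSet) -> CipherVector:
        vec = np.asarray(vec, dtype=float).ravel()
        sc = self.params.slot_count
        if vec.size > sc:
            raise PackingError(f"vector of length {vec.size} exceeds {sc} slots")
        slots = np.zeros(sc)
        slots[: vec.size] = vec
        return self._fresh(self._noisy(slots), vec.size, self.params.depth_budget, keys)

    def partial_decrypt(self, ct: CipherVector, key_share: PrivateKeyShare) -> PartialDecryption:
        proof = hashlib.sha256(
            b"partial:" + key_share.secret + ct.nonce.encode()
        ).hexdigest()
        return PartialDecryption(key_share.party, ct.nonce, proof)

    def decrypt(self, ct: CipherVector, keys: KeyShareSet, partials) -> np.ndarray:
        """Combine one valid partial decryption per party."""
        if ct.key_id != keys.key_id:
            raise KeyMismatchError("ciphertext was not encrypted under this key")
        got = {p.party for p in partials if p.ct_nonce == ct.nonce}
        if got != set(keys.parties):
            missing = set(keys.parties) - got
            raise DecryptionError(f"missing partial decryption from: {sorted(missing)}")
        for p in partials:
            if p.ct_nonce != ct.nonce:
                continue
            expect = hashlib.sha256(
                b"partial:" + keys.share_for(p.party).secret + ct.nonce.encode()
            ).hexdigest()
            if p.proof != expect:
                raise DecryptionError(f"invalid partial decryption from {p.party}")
        slots = self._noisy(ct._payload_for(self))
        return slots[: ct.n_slots_used].copy()

    # ------------------------------------------------------------- arithmetic
    def _coerce_plain(self, other, n_used) -> np.ndarray:
        arr = np.asarray(other).ravel()
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(float)
        if arr.size == 1:
            arr = np.full(n_used, arr[0], dtype=arr.dtype)
        if arr.size > self.params.slot_count:
            raise PackingError("plaintext operand exceeds slot count")
        out = np.zeros(self.params.slot_count, dtype=arr.dtype)
        out[: arr.size] = arr
        return out

    def add(self, ct: CipherVector, other) -> CipherVector:
        a = ct._payload_for(self)
        if isinstance(other, CipherVector):
            if other.key_id != ct.key_id:
                raise KeyMismatchError("key mismatch in h_add")
            b = other._payload_for(self)
            return self._derived(
                ct,
                self._noisy(a + b),
                n_used=max(ct.n_slots_used, other.n_slots_used),
                level=min(ct.level, other.level),
            )
        return self._derived(ct, self._noisy(a + self._coerce_plain(other, ct.n_slots_used)))

    def mul(self, ct: CipherVector, other) -> CipherVector:
        a = ct._payload_for(self)
        if isinstance(other, CipherVector):
            if other.key_id != ct.key_id:
                raise KeyMismatchError("key mismatch in h_mul")
            lvl = min(ct.level, other.level)
            if lvl < 1:
                raise DepthError("multiplicative depth exhausted")
            b = other._payload_for(self)
            return self._derived(
                ct,
                self._noisy(a * b),
                n_used=max(ct.n_slots_used, other.n_slots_used),
                level=lvl - 1,
            )
        if ct.level < 1:
            raise DepthError("multiplicative depth exhausted")
        plain = self._coerce_plain(other, ct.n_slots_used)
        return self._derived(ct, self._noisy(a * plain), level=ct.level - 1)

    def rotate(self, ct: CipherVector, r: int) -> CipherVector:
        a = ct._payload_for(self)
        return self._derived(ct, self._noisy(np.roll(a, -int(r))))


# ------------------------------------------------------------- functional API

def h_encrypt(vec, keys: KeyShareSet, backend: ReferenceBackend) -> CipherVector:
    return backend.encrypt(vec, keys)


def collab_decrypt(ct: CipherVector, keys: KeyShareSet, backend: ReferenceBackend,
                   parties=None) -> np.ndarray:
    """Full collaborative decryption: every party emits a partial."""
    parties = keys.parties if parties is None else parties
    partials = [backend.partial_decrypt(ct, keys.share_for(p)) for p in parties]
    return backend.decrypt(ct, keys, partials)


def h_add(ct: CipherVector, other) -> CipherVector:
    return ct.backend.add(ct, other)


def h_mul(ct: CipherVector, other) -> CipherVector:
    return ct.backend.mul(ct, other)


def h_rotate(ct: CipherVector, r: int) -> CipherVector:
    return ct.backend.rotate(ct, r)


def h_total_sum(ct: CipherVector, n_used: int | None = None) -> CipherVector:
    """Log2 rotation tree; slot 0 of the result holds the sum of the used
    slots (unused slots are zero by the encryption contract)."""
    n = ct.n_slots_used if n_used is None else n_used
    shift = 1
    out = ct
    while shift < n:
        out = h_add(out, h_rotate(out, shift))
        shift <<= 1
    return out


def h_masked_inner(ct: CipherVector, indicator) -> CipherVector:
    """<indicator, x> in slot 0, for a plaintext 0/1 indicator vector."""
    ind = np.asarray(indicator, dtype=float).ravel()
    if ind.size != ct.n_slots_used:
        raise PackingError(
            f"indicator length {ind.size} != used slots {ct.n_slots_used}"
        )
    return h_total_sum(h_mul(ct, ind), ct.n_slots_used)


class EncryptedVector:
    """A real vector of arbitrary length packed into ceil(L/slot_count)
    ciphertext chunks."""

    def __init__(self, chunks: list[CipherVector], length: int) -> None:
        self.chunks = chunks
        self.length = length

    @classmethod
    def encrypt(cls, vec, keys: KeyShareSet, backend: ReferenceBackend) -> "EncryptedVector":
        vec = np.asarray(vec, dtype=float).ravel()
        sc = backend.params.slot_count
        chunks = [
            backend.encrypt(vec[i : i + sc], keys) for i in range(0, vec.size, sc)
        ]
        if vec.size == 0:
            chunks = [backend.encrypt(np.zeros(0), keys)]
        return cls(chunks, vec.size)

    @property
    def n_ciphertexts(self) -> int:
        return len(self.chunks)

    def decrypt(self, keys: KeyShareSet, backend: ReferenceBackend) -> np.ndarray:
        return np.concatenate(
            [collab_decrypt(c, keys, backend) for c in self.chunks]
        )[: self.length]

    def add(self, other: "EncryptedVector") -> "EncryptedVector":
        if other.length != self.length:
            raise PackingError("length mismatch in encrypted add")
        return EncryptedVector(
            [h_add(a, b) for a, b in zip(self.chunks, other.chunks)], self.length
        )

    def masked_inner(self, indicator) -> CipherVector:
        """<indicator, x> in slot 0, summed homomorphically across chunks."""
        ind = np.asarray(indicator, dtype=float).ravel()
        if ind.size != self.length:
            raise PackingError("indicator length mismatch")
        sc = self.chunks[0].backend.params.slot_count
        acc = None
        for i, ct in enumerate(self.chunks):
            part = h_masked_inner(ct, ind[i * sc : i * sc + ct.n_slots_used])
            acc = part if acc is None else h_add(acc, part)
        return acc
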