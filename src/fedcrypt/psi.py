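"""Private set intersection over participant identifiers.

Commutative-masking (Diffie-Hellman) PSI in the quadratic-residue subgroup
of a safe-prime MODP group: each party hashes its identifiers into the
group, exponentiates with its own secret, exchanges the masked encodings,
re-exponentiates the other side's, and matches doubly masked values.
Both data owners learn exactly the common identifiers, canonically sorted;
the transcript carries only masked group elements.

The 2048-bit group is the conservative choice; smaller well-known groups
are available for in-process demo runs where many intersections are
executed. Semi-honest model throughout.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field

from fedcrypt.transcript import Transcript

__all__ = ["IdSet", "LinkageMap", "psi_intersect", "psi_multi", "MODP_PRIMES"]

# Safe primes for the commutative-masking group. 768/1024/2048 are the
# well-known IKE/Oakley MODP groups; 256 is a demo-grade group for
# in-process simulation runs that execute many intersections (it is NOT a
# cryptographically strong choice and exists for throughput only).
MODP_PRIMES = {
    256: int(
        "9c02e8cc7887e4042298a0befd358bb859d0ff8c5878910699581f80664e697f",
        16,
    ),
    768: int(
        "FFFFFFFFFFFFFFFFC90FDAA22168C234C4C6628B80DC1CD129024E088A67CC74"
        "020BBEA63B139B22514A08798E3404DDEF9519B3CD3A431B302B0A6DF25F1437"
        "4FE1356D6D51C245E485B576625E7EC6F44C42E9A63A3620FFFFFFFFFFFFFFFF",
        16,
    ),
    1024: int(
        "FFFFFFFFFFFFFFFFC90FDAA22168C234C4C6628B80DC1CD129024E088A67CC74"
        "020BBEA63B139B22514A08798E3404DDEF9519B3CD3A431B302B0A6DF25F1437"
        "4FE1356D6D51C245E485B576625E7EC6F44C42E9A637ED6B0BFF5CB6F406B7ED"
        "EE386BFB5A899FA5AE9F24117C4B1FE649286651ECE65381FFFFFFFFFFFFFFFF",
        16,
    ),
    2048: int(
        "FFFFFFFFFFFFFFFFC90FDAA22168C234C4C6628B80DC1CD129024E088A67CC74"
        "020BBEA63B139B22514A08798E3404DDEF9519B3CD3A431B302B0A6DF25F1437"
        "4FE1356D6D51C245E485B576625E7EC6F44C42E9A637ED6B0BFF5CB6F406B7ED"
        "EE386BFB5A899FA5AE9F24117C4B1FE649286651ECE45B3DC2007CB8A163BF05"
        "98DA48361C55D39A69163FA8FD24CF5F83655D23DCA3AD961C62F356208552BB"
        "9ED529077096966D670C354E4ABC9804F1746C08CA18217C32905E462E36CE3B"
        "E39E772C180E86039B2783A2EC07A28FB5C55DF06F4C52C9DE2BCBF695581718"
        "3995497CEA956AE515D2261898FA051015728E5A8AACAA68FFFFFFFFFFFFFFFF",
        16,
    ),
}


@dataclass(frozen=True)
class IdSet:
    """A party's set of opaque participant identifiers."""

    ids: tuple[str, ...]
    party: str

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError(f"duplicate identifiers in {self.party}'s set")


@dataclass(frozen=True)
class LinkageMap:
    """Common identifiers (canonical lexicographic order) plus, per party,
    the row index of each common identifier in that party's original
    ordering."""

    common_ids: tuple[str, ...]
    row_index: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n_common(self) -> int:
        return len(self.common_ids)


def _hash_to_group(identifier: str, p: int) -> int:
    h = int.from_bytes(hashlib.sha256(identifier.encode()).digest() * 4, "big")
    return pow(h % p, 2, p)  # land in the prime-order QR subgroup


def _mask(elems, secret: int, p: int) -> list[int]:
    return [pow(e, secret, p) for e in elems]


def _log_masked(transcript: Transcript | None, party: str, elems) -> None:
    if transcript is None:
        return
    for e in elems:
        digest = hashlib.sha256(e.to_bytes((e.bit_length() + 7) // 8, "big")).hexdigest()
        transcript.log("psi", f"masked_id:{party}", digest[:24])


def psi_intersect(
    local: IdSet,
    remote: IdSet,
    group_bits: int = 2048,
    seed: int | None = None,
    transcript: Transcript | None = None,
) -> LinkageMap:
    """Two-party DH-PSI; both parties learn X intersect Y and nothing else."""
    if group_bits not in MODP_PRIMES:
        raise ValueError(f"no MODP group of {group_bits} bits")
    p = MODP_PRIMES[group_bits]
    q = (p - 1) // 2
    rng = random.Random(seed)
    # short exponents (256-bit) in the large groups: standard DH practice
    exp_bound = min(q, 1 << 256)
    a = rng.randrange(2, exp_bound)  # local secret
    b = rng.randrange(2, exp_bound)  # remote secret

    x_elems = [_hash_to_group(i, p) for i in local.ids]
    y_elems = [_hash_to_group(i, p) for i in remote.ids]

    x_a = _mask(x_elems, a, p)  # local -> remote
    y_b = _mask(y_elems, b, p)  # remote -> local
    _log_masked(transcript, local.party, x_a)
    _log_masked(transcript, remote.party, y_b)

    x_ab = _mask(x_a, b, p)  # remote re-masks local's encodings
    y_ba = _mask(y_b, a, p)  # local re-masks remote's encodings
    _log_masked(transcript, remote.party, x_ab)
    _log_masked(transcript, local.party, y_ba)

    remote_double = set(y_ba)
    common = sorted(
        idx for idx, e in zip(local.ids, x_ab) if e in remote_double
    )
    return _linkage(common, [local, remote])


def _linkage(common: list[str], id_sets) -> LinkageMap:
    row_index = {}
    for s in id_sets:
        pos = {i: r for r, i in enumerate(s.ids)}
        row_index[s.party] = [pos[i] for i in common]
    return LinkageMap(tuple(common), row_index)


def psi_multi(
    sets,
    group_bits: int = 2048,
    seed: int | None = None,
    transcript: Transcript | None = None,
) -> LinkageMap:
    """Multi-party PSI by pairwise reduction through the first party
    (the coordinator); only the final intersection is revealed."""
    sets = list(sets)
    if len(sets) < 3:
        raise ValueError("psi_multi needs >= 3 parties (use psi_intersect)")
    current = set(sets[0].ids)
    for j, other in enumerate(sets[1:], start=1):
        if not current:
            break
        step = psi_intersect(
            IdSet(tuple(sorted(current)), sets[0].party),
            other,
            group_bits=group_bits,
            seed=None if seed is None else seed + j,
            transcript=transcript,
        )
        current = set(step.common_ids)
    return _linkage(sorted(current), sets)
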