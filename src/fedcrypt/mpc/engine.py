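"""Semi-honest additive-sharing arithmetic with a trusted dealer.

All parties run in one process; "communication" is the append-only
transcript of opened (masked) values. The dealer draws Beaver triples and
comparison masks from its own seeded generator, emulating an offline
preprocessing phase.

Fixed-point multiplication uses probabilistic local-share truncation
(party 0 shifts its share as a nonnegative integer, the others shift the
negation): the result is exact up to n_parties-1 units in the last place,
and wraps with probability ~ n_parties * 2^(l+1-k) for operands of ring
magnitude 2^l. Callers needing many multiplications on large magnitudes
open a session with a wider ring.
"""

from __future__ import annotations

import hashlib
import math
import random
from dataclasses import dataclass, field

from fedcrypt.mpc.ring import (
    EncodingError,
    NumericDomainError,
    ProtocolError,
    RingParams,
    SessionError,
    centered,
    decode,
    encode,
)
from fedcrypt.transcript import Transcript

__all__ = [
    "MpcSession",
    "SecretShare",
    "BeaverTriple",
    "share",
    "reconstruct",
    "m_add",
    "m_add_pub",
    "m_mul_pub",
    "m_mul",
    "m_div",
    "m_inv_sqrt",
    "m_cmp",
]

# Goldschmidt reciprocal seed: x0 = _SEED_A - 2*d for d in (0, 1] keeps the
# initial error 1 - d*x0 strictly below 1, so the iteration always converges.
_SEED_A = 2.9142


def _derived_seed(seed: int, label: str) -> int:
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:8], "big")


@dataclass
class BeaverTriple:
    """Single-use multiplication triple: shares of (a, b, c) with c = a*b."""

    a: tuple[int, ...]
    b: tuple[int, ...]
    c: tuple[int, ...]
    used: bool = field(default=False)


class SecretShare:
    """A fixed-point value held as one additive share per party."""

    __slots__ = ("shares", "session")

    def __init__(self, shares, session: "MpcSession") -> None:
        self.shares = tuple(int(s) % session.params.modulus for s in shares)
        self.session = session

    def _check(self, other: "SecretShare") -> None:
        if other.session is not self.session:
            raise SessionError("shares belong to different sessions")

    # linear algebra on shares is local (no communication)
    def __add__(self, other):
        if isinstance(other, SecretShare):
            self._check(other)
            return SecretShare(
                [x + y for x, y in zip(self.shares, other.shares)],
                self.session,
            )
        return self.session.add_pub(self, float(other))

    __radd__ = __add__

    def __neg__(self):
        return SecretShare([-x for x in self.shares], self.session)

    def __sub__(self, other):
        if isinstance(other, SecretShare):
            return self + (-other)
        return self + (-float(other))

    def __rsub__(self, other):
        return (-self) + float(other)

    def __mul__(self, other):
        if isinstance(other, SecretShare):
            return self.session.mul(self, other)
        return self.session.mul_pub(self, float(other))

    __rmul__ = __mul__


class MpcSession:
    """In-process multiparty session: parties, dealer, transcript."""

    def __init__(
        self,
        params: RingParams | None = None,
        seed: int = 0,
        transcript: Transcript | None = None,
        session_id: str = "mpc",
        debug: bool = False,
    ) -> None:
        self.params = params or RingParams()
        self.session_id = session_id
        self.transcript = transcript or Transcript(session_id)
        self.debug = debug
        self._dealer_rng = random.Random(_derived_seed(seed, "dealer"))
        self._input_rng = random.Random(_derived_seed(seed, "input"))
        self._triples_issued = 0
        self.transcript.log(
            "session", "setup", None,
            params={"k": self.params.k, "f": self.params.f,
                    "stat_sec": self.params.stat_sec,
                    "n_parties": self.params.n_parties},
            seed_fingerprint=hashlib.sha256(str(seed).encode()).hexdigest()[:16],
        )

    # ------------------------------------------------------------------ input
    def _split(self, ring_value: int, rng) -> tuple[int, ...]:
        m = self.params.modulus
        others = [rng.getrandbits(self.params.k) for _ in range(self.params.n_parties - 1)]
        first = (ring_value - sum(others)) % m
        return (first, *others)

    def share(self, value: float) -> SecretShare:
        """Secret-share a real value (fixed-point encoded)."""
        return SecretShare(self._split(encode(value, self.params), self._input_rng), self)

    def share_ring(self, ring_value: int) -> SecretShare:
        return SecretShare(self._split(ring_value % self.params.modulus, self._input_rng), self)

    def const(self, value: float) -> SecretShare:
        """Public constant as a degenerate sharing (party 0 holds it)."""
        sh = [0] * self.params.n_parties
        sh[0] = encode(value, self.params)
        return SecretShare(sh, self)

    # ----------------------------------------------------------------- opening
    def open(self, x: SecretShare, tag: str) -> int:
        """All parties broadcast their shares; the ring value is logged."""
        v = sum(x.shares) % self.params.modulus
        self.transcript.log("open", tag, v)
        return v

    def reveal(self, x: SecretShare, name: str) -> float:
        """Open a declared protocol output."""
        return decode(self.open(x, f"reveal:{name}"), self.params)

    def reconstruct(self, x: SecretShare) -> float:
        """Open for debugging/tests; tagged as a declared reconstruction."""
        return decode(self.open(x, "reveal:reconstruct"), self.params)

    # ------------------------------------------------------------------ linear
    def add_pub(self, x: SecretShare, c: float) -> SecretShare:
        sh = list(x.shares)
        sh[0] = (sh[0] + encode(c, self.params)) % self.params.modulus
        return SecretShare(sh, self)

    def mul_pub_int(self, x: SecretShare, c: int) -> SecretShare:
        """Multiply by an exact public integer (no rescale needed)."""
        return SecretShare([s * c for s in x.shares], self)

    def mul_pub(self, x: SecretShare, c: float) -> SecretShare:
        ce = round(float(c) * self.params.scale)
        return self.trunc(self.mul_pub_int(x, ce), self.params.f)

    # -------------------------------------------------------------- truncation
    def trunc(self, x: SecretShare, bits: int) -> SecretShare:
        """Probabilistic right shift by `bits`.

        Two computing parties: party 0 shifts its share, party 1 shifts the
        negation of its own. The single borrow term contributes +1/2 ulp in
        expectation (cancelling the floor's -1/2), so the result is
        unbiased with error within ~±1 ulp; a wrap error occurs with
        probability ~2^(l+1-k) for ring magnitude 2^l. The construction
        does not extend to more ring-sharing parties (multiple wraps), and
        the protocol topology never needs it to: nonlinear steps always run
        between the two computing sites."""
        if bits <= 0:
            return x
        if self.params.n_parties != 2:
            raise ProtocolError(
                "fixed-point truncation requires exactly 2 computing parties"
            )
        m = self.params.modulus
        s0, s1 = x.shares
        return SecretShare(
            [s0 >> bits, (m - (((m - s1) % m) >> bits)) % m], self
        )

    # ------------------------------------------------------------------ dealer
    def triple(self) -> BeaverTriple:
        rng = self._dealer_rng
        k, mod = self.params.k, self.params.modulus
        a = rng.getrandbits(k)
        b = rng.getrandbits(k)
        c = (a * b) % mod
        self._triples_issued += 1
        return BeaverTriple(
            a=self._split(a, rng), b=self._split(b, rng), c=self._split(c, rng)
        )

    # ------------------------------------------------------------ multiplication
    def mul(
        self,
        x: SecretShare,
        y: SecretShare,
        triple: BeaverTriple | None = None,
        shift: int | None = None,
    ) -> SecretShare:
        """Beaver multiplication; rescales by 2^shift (default 2^f)."""
        x._check(y)
        if triple is None:
            triple = self.triple()
        if triple.used:
            raise ProtocolError("Beaver triple reuse")
        triple.used = True
        mod = self.params.modulus
        ta = SecretShare(triple.a, self)
        tb = SecretShare(triple.b, self)
        d = centered(self.open(x - ta, "beaver:d"), self.params)
        e = centered(self.open(y - tb, "beaver:e"), self.params)
        z = [
            (tc + d * sb + e * sa) % mod
            for tc, sb, sa in zip(triple.c, tb.shares, ta.shares)
        ]
        z[0] = (z[0] + d * e) % mod
        out = SecretShare(z, self)
        if shift is None:
            shift = self.params.f
        return self.trunc(out, shift)

    # ------------------------------------------------------------- comparison
    def cmp_ring(self, x: SecretShare, threshold_ring: int) -> SecretShare:
        """[x_ring >= threshold_ring] via dealer-assisted multiplicative
        sign masking: open (x - t) * r for a random positive r. The sign of
        the opening is the comparison bit (public to the computing parties;
        every protocol use corresponds to a declared output)."""
        d = SecretShare(
            [
                (s - (threshold_ring if i == 0 else 0)) % self.params.modulus
                for i, s in enumerate(x.shares)
            ],
            self,
        )
        r = self._dealer_rng.randrange(1, 1 << self.params.cmp_mask_bits)
        r_sh = SecretShare(self._split(r, self._dealer_rng), self)
        z_sh = self.mul(d, r_sh, shift=0)
        z = centered(self.open(z_sh, "cmp:masked"), self.params)
        bit = 1 if z >= 0 else 0
        return self.share(float(bit))

    def cmp(self, x: SecretShare, threshold: float) -> SecretShare:
        """[x >= threshold] as a shared 0/1 value."""
        return self.cmp_ring(x, encode(threshold, self.params))

    # --------------------------------------------------------------- division
    def _goldschmidt_iters(self, bound2: float, den_floor: float) -> int:
        dmin = max(den_floor / bound2, 2 ** -(self.params.f - 2))
        need = (0.7 * self.params.f + 8.0) / (_SEED_A * dmin)
        return max(8, min(72, math.ceil(math.log2(need)) + 1))

    def div(
        self,
        num: SecretShare,
        den: SecretShare,
        bound_pub: float,
        den_floor: float | None = None,
        iterations: int | None = None,
    ) -> SecretShare:
        """num/den for den in (0, bound_pub], via Goldschmidt iteration.

        The denominator is normalized by the next power of two above
        bound_pub (an exact shift); `den_floor` is a public lower bound on
        den used only to size the iteration count.
        """
        if bound_pub <= 0:
            raise NumericDomainError("bound_pub must be positive")
        mshift = max(0, math.ceil(math.log2(bound_pub)))
        bound2 = float(1 << mshift)
        if den_floor is None:
            den_floor = bound2 / 4096.0
        if iterations is None:
            iterations = self._goldschmidt_iters(bound2, den_floor)
        if self.debug:
            ok = decode(
                sum(self.cmp(den, 0.0).shares) % self.params.modulus, self.params
            )
            if ok < 0.5:
                raise NumericDomainError("nonpositive denominator")
        # Newton reciprocal on the scaled variable rt = B/den >= 1 (kept
        # large so truncation noise stays small relative to it):
        #   rt <- rt (2 - den*rt/B),   num/den = num*rt/B.
        # The /B steps are exact power-of-two shifts folded into the
        # multiplication rescale. Seeded with the affine approximation
        # rt0 = A - 2 den/B; the iteration is self-correcting, so only the
        # last step's truncation noise survives into the result.
        shift_b = self.params.f + mshift
        rt = self.add_pub(self.trunc(self.mul_pub_int(den, -2), mshift), _SEED_A)
        for _ in range(iterations):
            u = self.mul(den, rt, shift=shift_b)
            rt = self.mul(rt, self.add_pub(-u, 2.0))
        return self.mul(num, rt, shift=shift_b)

    # --------------------------------------------------------- inverse sqrt
    def inv_sqrt(
        self,
        a: SecretShare,
        bound_pub: float,
        floor_pub: float | None = None,
        iterations: int | None = None,
    ) -> SecretShare:
        """1/sqrt(a) for a in (0, bound_pub], by Newton's iteration
        y <- y(3 - a y^2)/2 on a normalized to (0, 1]."""
        if bound_pub <= 0:
            raise NumericDomainError("bound_pub must be positive")
        mhalf = max(0, math.ceil(math.log2(bound_pub) / 2.0))
        if floor_pub is None:
            floor_pub = bound_pub / 4096.0
        floor_pub = max(floor_pub, 2 ** -(self.params.f - 2))
        if iterations is None:
            # y starts at 2^-mhalf and grows by at most ~1.5x per step
            target = float(1 << mhalf) / math.sqrt(floor_pub)
            iterations = max(10, min(70, math.ceil(math.log(max(target, 1.5)) / math.log(1.5)) + 10))
        # y0 = 1/sqrt(4^mhalf) <= 1/sqrt(a); iterate on the full-precision
        # a, associating a*y^2 as (a*y)*y so truncation noise on the tiny
        # y^2 is never amplified by a large a
        y = self.const(2.0 ** -mhalf)
        for _ in range(iterations):
            ay = self.mul(a, y)
            ay2 = self.mul(ay, y)
            u = self.add_pub(-ay2, 3.0)
            y = self.mul(y, u, shift=self.params.f + 1)  # includes /2
        return y


# ------------------------------------------------------------ functional API

def share(value: float, session: MpcSession) -> SecretShare:
    return session.share(value)


def reconstruct(x: SecretShare) -> float:
    return x.session.reconstruct(x)


def m_add(a: SecretShare, b: SecretShare) -> SecretShare:
    return a + b


def m_add_pub(a: SecretShare, c: float) -> SecretShare:
    return a + c


def m_mul_pub(a: SecretShare, c: float) -> SecretShare:
    return a * c


def m_mul(a: SecretShare, b: SecretShare, triple: BeaverTriple | None = None) -> SecretShare:
    return a.session.mul(a, b, triple=triple)


def m_div(
    num: SecretShare,
    den: SecretShare,
    bound_pub: float,
    den_floor: float | None = None,
) -> SecretShare:
    return num.session.div(num, den, bound_pub, den_floor=den_floor)


def m_inv_sqrt(
    a: SecretShare, bound_pub: float, floor_pub: float | None = None
) -> SecretShare:
    return a.session.inv_sqrt(a, bound_pub, floor_pub=floor_pub)


def m_cmp(a: SecretShare, threshold_pub: float) -> SecretShare:
    return a.session.cmp(a, threshold_pub)
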