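"""Ring parameters and fixed-point encoding.

Values live in Z_{2^k} as two's-complement integers scaled by 2^f
fractional bits. The default k=64 / f=16 matches a SPDZ2k-style
semi-honest deployment with 40-bit statistical security; sessions that
need more multiplicative headroom (the federated protocol layer) open
wider rings, which only changes arithmetic on Python integers.
"""

from __future__ import annotations

from dataclasses import dataclass


class EncodingError(ValueError):
    """Value outside the representable fixed-point range."""


class SessionError(RuntimeError):
    """Shares from mismatched sessions/parameters were combined."""


class ProtocolError(RuntimeError):
    """Protocol misuse, e.g. Beaver-triple reuse."""


class NumericDomainError(ValueError):
    """Input outside a nonlinear primitive's domain (e.g. nonpositive
    denominator)."""


@dataclass(frozen=True)
class RingParams:
    """Shared-arithmetic parameters all parties must agree on.

    k: ring bit-width; f: fractional bits; stat_sec: statistical security
    for masked openings; n_parties: number of computing parties.
    """

    k: int = 64
    f: int = 16
    stat_sec: int = 40
    n_parties: int = 2

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("ring bit-width too small")
        if not (0 < self.f < self.k / 2):
            raise ValueError("need 0 < f < k/2")
        if self.n_parties < 2:
            raise ValueError("need >= 2 parties")
        if self.stat_sec < 1:
            raise ValueError("stat_sec must be positive")

    @property
    def modulus(self) -> int:
        return 1 << self.k

    @property
    def scale(self) -> int:
        return 1 << self.f

    @property
    def max_magnitude(self) -> float:
        """Largest encodable magnitude, with two bits of headroom."""
        return float(1 << (self.k - self.f - 2))

    @property
    def cmp_mask_bits(self) -> int:
        # Multiplicative sign-mask width for comparisons: as many bits as
        # stat_sec allows while keeping |diff| * mask inside the ring for
        # operands up to ~2^(k - f - 30) in magnitude.
        return max(8, min(self.stat_sec, self.k - self.f - 30))


def encode(value: float, params: RingParams) -> int:
    """Real -> ring element at scale 2^f (round to nearest)."""
    scaled = round(float(value) * params.scale)
    if abs(value) >= params.max_magnitude:
        raise EncodingError(
            f"|{value}| exceeds fixed-point headroom 2^{params.k - params.f - 2}"
        )
    return scaled % params.modulus


def decode(ring_value: int, params: RingParams) -> float:
    """Ring element -> real, via the centered representative."""
    m = params.modulus
    v = ring_value % m
    if v >= m >> 1:
        v -= m
    return v / params.scale


def centered(ring_value: int, params: RingParams) -> int:
    """Signed integer representative in [-2^(k-1), 2^(k-1))."""
    m = params.modulus
    v = ring_value % m
    return v - m if v >= m >> 1 else v
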