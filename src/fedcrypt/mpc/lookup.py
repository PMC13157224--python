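"""MLookup: private table lookup of p-values on a tiered grid.

The grid holds p-values at 0.001 resolution on (0, 0.01], 0.01 on
(0.01, 0.1] and 0.1 on (0.1, 1.0] - finest where it matters most. For a
given distribution (F with public degrees of freedom; a squared t
statistic is looked up as F(1, nu)) the breakpoints are the critical
values of the statistic at the midpoints between adjacent grid p-values.
The secret-shared statistic is compared against every breakpoint; the
monotone ladder of comparison bits selects, via an oblivious inner product
with the grid, the p-value nearest (in p-space) to the statistic's true
upper-tail p. Only the selected p is revealed.

Tie rule: a statistic exactly on a breakpoint snaps to the LARGER p
(conservative). Statistics beyond the lowest breakpoint clamp to the
smallest grid p with an at-resolution-floor flag.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps

from fedcrypt.mpc.engine import MpcSession, SecretShare

__all__ = ["PValueGrid", "m_lookup_pvalue", "LookupResult", "default_p_points"]

# Degrees of freedom above this use the large-df (normal) approximation,
# i.e. F(d1, inf) = chi2(d1)/d1.
MAX_TABLE_DF = 200


def default_p_points() -> tuple[float, ...]:
    pts = [round(0.001 * i, 3) for i in range(1, 11)]       # 0.001 .. 0.01
    pts += [round(0.01 * i, 2) for i in range(2, 11)]        # 0.02 .. 0.1
    pts += [round(0.1 * i, 1) for i in range(2, 11)]         # 0.2 .. 1.0
    return tuple(pts)


@dataclass(frozen=True)
class PValueGrid:
    """Tiered p grid plus per-df critical-value breakpoints.

    breakpoints[j] is the statistic's critical value at the p-space
    midpoint between p_points[j] and p_points[j+1]; it is strictly
    decreasing in j for a fixed distribution.
    """

    distribution: str  # "f"
    df1: int
    df2: int | None  # None -> large-df/normal approximation
    p_points: tuple[float, ...]
    breakpoints: tuple[float, ...]

    @classmethod
    def for_f(cls, df1: int, df2: int | None) -> "PValueGrid":
        if df1 < 1 or (df2 is not None and df2 < 1):
            raise ValueError(f"unsupported degrees of freedom ({df1}, {df2})")
        if df2 is not None and df2 > MAX_TABLE_DF:
            df2 = None
        pts = default_p_points()
        mids = [(a + b) / 2.0 for a, b in zip(pts[:-1], pts[1:])]
        crit = [_isf_f(p, df1, df2) for p in mids]
        return cls("f", df1, df2, pts, tuple(crit))

    def true_p(self, stat: float) -> float:
        return _sf_f(stat, self.df1, self.df2)

    def nearest_p(self, p_true: float) -> float:
        """Snap a true p to the nearest grid point (midpoint ties go to the
        larger p); values below the smallest midpoint clamp to the floor."""
        pts = np.asarray(self.p_points)
        # midpoints rounded so that an exact decimal tie (e.g. 0.85 between
        # 0.8 and 0.9) is recognized despite float summation error
        mids = np.round((pts[:-1] + pts[1:]) / 2.0, 12)
        idx = int(np.searchsorted(mids, p_true, side="right"))
        return float(pts[idx])

    def to_json(self) -> str:
        return json.dumps(
            {
                "distribution": self.distribution,
                "df": [self.df1, self.df2],
                "p_points": list(self.p_points),
                "breakpoints": list(self.breakpoints),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PValueGrid":
        d = json.loads(text)
        return cls(
            d["distribution"],
            d["df"][0],
            d["df"][1],
            tuple(d["p_points"]),
            tuple(d["breakpoints"]),
        )


@lru_cache(maxsize=4096)
def _grid_cache(df1: int, df2: int | None) -> PValueGrid:
    return PValueGrid.for_f(df1, df2)


def grid_for(df1: int, df2: int | None) -> PValueGrid:
    """Cached grid for an F(df1, df2) statistic (df2=None -> large-df)."""
    return _grid_cache(int(df1), None if df2 is None else int(df2))


def _isf_f(p: float, df1: int, df2: int | None) -> float:
    if df2 is None:
        return float(sps.chi2.isf(p, df1) / df1)
    return float(sps.f.isf(p, df1, df2))


def _sf_f(stat: float, df1: int, df2: int | None) -> float:
    if df2 is None:
        return float(sps.chi2.sf(stat * df1, df1))
    return float(sps.f.sf(stat, df1, df2))


@dataclass(frozen=True)
class LookupResult:
    p_value: float
    at_resolution_floor: bool


def m_lookup_pvalue(
    stat: SecretShare, grid: PValueGrid, session: MpcSession | None = None
) -> LookupResult:
    """Obliviously map a secret-shared nonnegative statistic to the grid
    p-value nearest its true upper-tail p; only that p is revealed."""
    sess = session or stat.session
    f = sess.params.f
    npts = len(grid.p_points)
    # strict ">" against breakpoint c at ring resolution: [stat >= c_ring + 1]
    bits: list[SecretShare] = []
    for c in grid.breakpoints:
        c_ring = (math.floor(c * sess.params.scale) + 1) % sess.params.modulus
        bits.append(sess.cmp_ring(stat, c_ring))
    # Breakpoints decrease with the grid index, so the comparison bits form
    # a non-decreasing ladder; the selected grid index is the first set bit
    # (or the last index when no bit is set). One-hot selection by adjacent
    # differences: sel_i = b_i - b_{i-1} with virtual b_{-1}=0, b_{npts-1}=1.
    p_sh = sess.const(0.0)
    for i in range(npts):
        cur = bits[i] if i < npts - 1 else None  # virtual trailing 1
        prev = bits[i - 1] if i > 0 else None  # virtual leading 0
        if cur is None and prev is None:
            sel = sess.const(1.0)
        elif cur is None:
            sel = sess.const(1.0) - prev
        elif prev is None:
            sel = cur
        else:
            sel = cur - prev
        p_sh = p_sh + sess.mul_pub(sel, grid.p_points[i])
    p_open = sess.reveal(p_sh, "p_value")
    pts = np.asarray(grid.p_points)
    p = float(pts[int(np.argmin(np.abs(pts - p_open)))])
    return LookupResult(p_value=p, at_resolution_floor=(p == grid.p_points[0]))
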