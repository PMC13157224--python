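"""Federated secure statistics across a genomic site and phenotype site(s).

Division of labour: heavy linear aggregation (per-group sums and sums of
squares of the attribute vector) runs under SIMD-packed homomorphic
encryption via masked inner products with the genomic site's private
group-indicator vectors; the handful of nonlinear finishing steps
(divisions, inverse square roots, comparisons, the p-value table lookup)
run under additive secret sharing after an HE->MPC conversion. Only each
protocol's declared outputs are revealed; group sizes n_k enter as the
genomic site's private MPC inputs (only the total N and the number of
groups K are public).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from fedcrypt.he.bridge import he2mpc
from fedcrypt.he.engine import (
    EncryptedVector,
    HEParams,
    KeyShareSet,
    ReferenceBackend,
    mp_keygen,
)
from fedcrypt.mpc.engine import MpcSession, SecretShare
from fedcrypt.mpc.lookup import grid_for, m_lookup_pvalue, MAX_TABLE_DF
from fedcrypt.mpc.ring import RingParams
from fedcrypt.stat_core import AnovaResult, MetaResult, TTestResult
from fedcrypt.transcript import Transcript

__all__ = [
    "AttributeBounds",
    "FederatedSession",
    "SecureAttribute",
    "ProtocolAbort",
    "SecureSMD",
    "secure_anova",
    "secure_ttest",
    "secure_smd",
    "secure_meta",
]


class ProtocolAbort(RuntimeError):
    """A protocol refused to run (degenerate grouping, tiny stratum...)."""


@dataclass(frozen=True)
class AttributeBounds:
    """Public magnitude bounds for the analyzed attribute, declared in
    configuration (NOT derived from data): absolute value cap per entry
    and a plausible range for the within-group standard deviation."""

    value_max: float = 256.0   # mmHg; covers any blood-pressure reading
    sd_max: float = 32.0
    sd_min: float = 2.0

    @property
    def var_max(self) -> float:
        return self.sd_max ** 2

    @property
    def var_min(self) -> float:
        return self.sd_min ** 2


# Wider ring than the k=64 primitive default: the protocol pipelines chain
# many fixed-point multiplications on group aggregates (sums of squares up
# to ~N * value_max^2), and the extra headroom makes the probabilistic-
# truncation wrap risk negligible, while f=40 keeps the absolute
# fixed-point noise on those aggregates far below the smallest statistics
# the pipelines divide into.
DEFAULT_PROTOCOL_RING = RingParams(k=192, f=40, stat_sec=40, n_parties=2)


class FederatedSession:
    """One cohort's protocol session: joint HE key between the genomic
    site and the phenotype site(s), an MPC session between the two
    computing parties, and a shared transcript."""

    def __init__(
        self,
        n_phenotype_sites: int = 1,
        seed: int = 0,
        he_params: HEParams | None = None,
        ring_params: RingParams | None = None,
        bounds: AttributeBounds | None = None,
        session_id: str = "cohort",
    ) -> None:
        n_parties = 1 + n_phenotype_sites
        self.parties = ("genomic",) + tuple(
            f"phenotype{i}" for i in range(n_phenotype_sites)
        )
        self.he_params = he_params or HEParams(n_parties=n_parties)
        if self.he_params.n_parties != n_parties:
            raise ValueError("he_params.n_parties inconsistent with site count")
        self.bounds = bounds or AttributeBounds()
        self.transcript = Transcript(session_id)
        self.backend = ReferenceBackend(self.he_params, seed=seed)
        self.keys: KeyShareSet = mp_keygen(self.he_params, self.parties, seed=seed)
        self.mpc = MpcSession(
            ring_params or DEFAULT_PROTOCOL_RING,
            seed=seed,
            transcript=self.transcript,
            session_id=session_id,
        )

    # -------------------------------------------------------------- helpers
    def convert_slot(self, ct, value_bound: float) -> SecretShare:
        return he2mpc(ct, 0, self.keys, self.backend, self.mpc, value_bound)


class SecureAttribute:
    """Phenotype-site attribute vector, encrypted once and reusable across
    protocols: ciphertexts of x and of x*x, aligned to the linkage order.
    Under hybrid partitioning each phenotype site encrypts its own slice
    (zeros elsewhere) and the slices are summed homomorphically."""

    def __init__(self, session: FederatedSession, ev_x, ev_x2, n: int) -> None:
        self.session = session
        self.ev_x = ev_x
        self.ev_x2 = ev_x2
        self.n = n

    @classmethod
    def from_parts(cls, session: FederatedSession, parts) -> "SecureAttribute":
        parts = [np.asarray(p, dtype=float) for p in parts]
        n = parts[0].size
        if any(p.size != n for p in parts):
            raise ValueError("phenotype slices must share the linkage length")
        vmax = session.bounds.value_max
        if any(np.max(np.abs(p)) > vmax for p in parts if p.size):
            raise ValueError("attribute exceeds declared public bound")
        ev_x = ev_x2 = None
        for p in parts:
            ex = EncryptedVector.encrypt(p, session.keys, session.backend)
            ex2 = EncryptedVector.encrypt(p * p, session.keys, session.backend)
            ev_x = ex if ev_x is None else ev_x.add(ex)
            ev_x2 = ex2 if ev_x2 is None else ev_x2.add(ex2)
        session.transcript.log(
            "he", "pack", None, n=n, n_ciphertexts=ev_x.n_ciphertexts,
            slot_count=session.backend.params.slot_count,
        )
        expected = max(1, math.ceil(n / session.backend.params.slot_count))
        assert ev_x.n_ciphertexts == expected
        return cls(session, ev_x, ev_x2, n)


@dataclass(frozen=True)
class SecureSMD:
    """Revealed outputs of the secure SMD protocol."""

    g: float
    var_g: float


def _validate_indicators(indicators, n: int, *, partition: bool) -> np.ndarray:
    c = np.asarray(indicators)
    if c.ndim != 2 or c.shape[1] != n:
        raise ValueError(f"indicators must be K x {n}")
    if not np.isin(c, (0, 1)).all():
        raise ValueError("indicator entries must be 0/1")
    if partition and not (c.sum(axis=0) == 1).all():
        raise ProtocolAbort("every sample must belong to exactly one group")
    sizes = c.sum(axis=1)
    if (sizes < 2).any():
        raise ProtocolAbort(
            f"degenerate grouping: group sizes {sizes.astype(int).tolist()}"
        )
    return c.astype(float)


def _group_aggregates(session: FederatedSession, attr: SecureAttribute, c: np.ndarray):
    """Per-group (S_k, SS_k, n_k) as MPC shares.

    S_k and SS_k come from homomorphic masked inner products converted via
    he2mpc; n_k is the genomic site's private input.
    """
    n = attr.n
    vmax = session.bounds.value_max
    s_shares, ss_shares, n_shares = [], [], []
    for row in c:
        ct_s = attr.ev_x.masked_inner(row)
        ct_ss = attr.ev_x2.masked_inner(row)
        s_shares.append(session.convert_slot(ct_s, n * vmax))
        ss_shares.append(session.convert_slot(ct_ss, n * vmax * vmax))
        n_shares.append(session.mpc.share(float(row.sum())))
    return s_shares, ss_shares, n_shares


def secure_anova(session: FederatedSession, indicators, attr) -> AnovaResult:
    """Secure one-way ANOVA: F = MSB/MSW with p from the tiered grid.

    Reveals only (F, df_between, df_within, grid p)."""
    if not isinstance(attr, SecureAttribute):
        attr = SecureAttribute.from_parts(session, attr)
    c = _validate_indicators(indicators, attr.n, partition=True)
    k, n = c.shape
    if n <= k:
        raise ProtocolAbort("need N > K")
    mpc = session.mpc
    b = session.bounds
    s_sh, ss_sh, n_sh = _group_aggregates(session, attr, c)

    s_tot = s_sh[0]
    ss_tot = ss_sh[0]
    for x in s_sh[1:]:
        s_tot = s_tot + x
    for x in ss_sh[1:]:
        ss_tot = ss_tot + x
    # T2 = sum_k S_k^2 / n_k
    t2 = None
    for s_k, nk in zip(s_sh, n_sh):
        term = mpc.div(mpc.mul(s_k, s_k), nk, bound_pub=n, den_floor=2.0)
        t2 = term if t2 is None else t2 + term
    ssb = t2 - mpc.mul_pub(mpc.mul(s_tot, s_tot), 1.0 / n)
    ssw = ss_tot - t2
    msb = mpc.mul_pub(ssb, 1.0 / (k - 1))
    msw = mpc.mul_pub(ssw, 1.0 / (n - k))
    f_sh = mpc.div(msb, msw, bound_pub=2 * b.var_max, den_floor=b.var_min / 4)
    lookup = m_lookup_pvalue(f_sh, grid_for(k - 1, n - k), mpc)
    f_stat = mpc.reveal(f_sh, "F")
    return AnovaResult(
        f_stat=f_stat, df_between=k - 1, df_within=n - k, p_value=lookup.p_value
    )


def _means_and_variances(session, s_sh, ss_sh, n_sh, n_public: int):
    """Per-group mean and unbiased variance from (S, SS, n) shares."""
    mpc = session.mpc
    means, variances, errs = [], [], []
    for s_k, ss_k, nk in zip(s_sh, ss_sh, n_sh):
        m = mpc.div(s_k, nk, bound_pub=n_public, den_floor=2.0)
        e = ss_k - mpc.mul(s_k, m)  # (n_k - 1) * s_k^2
        v = mpc.div(e, nk + (-1.0), bound_pub=n_public, den_floor=1.0)
        means.append(m)
        variances.append(v)
        errs.append(e)
    return means, variances, errs


def secure_ttest(session: FederatedSession, indicators, attr) -> TTestResult:
    """Secure Welch's t-test.

    Computes t^2 = (m1-m2)^2 n1 n2 / (s1^2 n2 + s2^2 n1) in shared form
    (avoiding a secure square root), looks the squared statistic up against
    F(1, nu), and reveals (t^2, its sign bit, rounded nu, grid p)."""
    if not isinstance(attr, SecureAttribute):
        attr = SecureAttribute.from_parts(session, attr)
    c = _validate_indicators(indicators, attr.n, partition=False)
    if c.shape[0] != 2:
        raise ValueError("t-test needs exactly 2 indicator rows")
    if (c.sum(axis=0) > 1).any():
        raise ProtocolAbort("t-test groups must be disjoint")
    mpc = session.mpc
    b = session.bounds
    n = attr.n
    s_sh, ss_sh, n_sh = _group_aggregates(session, attr, c)
    (m1, m2), (v1, v2), _ = _means_and_variances(session, s_sh, ss_sh, n_sh, n)
    n1, n2 = n_sh
    delta = m1 - m2
    den = mpc.mul(v1, n2) + mpc.mul(v2, n1)  # s1^2 n2 + s2^2 n1
    num = mpc.mul(mpc.mul(delta, delta), mpc.mul(n1, n2))
    t2_sh = mpc.div(
        num, den, bound_pub=2 * b.var_max * n, den_floor=2 * b.var_min
    )
    # Welch-Satterthwaite: nu = den^2 / (s1^4 n2^2/(n1-1) + s2^4 n1^2/(n2-1))
    u1 = mpc.div(
        mpc.mul(mpc.mul(v1, v1), mpc.mul(n2, n2)),
        n1 + (-1.0),
        bound_pub=n,
        den_floor=1.0,
    )
    u2 = mpc.div(
        mpc.mul(mpc.mul(v2, v2), mpc.mul(n1, n1)),
        n2 + (-1.0),
        bound_pub=n,
        den_floor=1.0,
    )
    nu_sh = mpc.div(
        mpc.mul(den, den),
        u1 + u2,
        bound_pub=2 * b.var_max ** 2 * n * n,
        den_floor=4 * b.var_min ** 2 / n,
    )
    nu = mpc.reveal(nu_sh, "nu")  # df is treated as plaintext
    nu_round = int(min(max(round(nu), 1), MAX_TABLE_DF + 1))
    grid = grid_for(1, nu_round if nu_round <= MAX_TABLE_DF else None)
    lookup = m_lookup_pvalue(t2_sh, grid, mpc)
    sign_bit = mpc.reveal(mpc.cmp(delta, 0.0), "t_sign")
    t2 = mpc.reveal(t2_sh, "t_squared")
    t = (1.0 if sign_bit >= 0.5 else -1.0) * math.sqrt(max(t2, 0.0))
    return TTestResult(t_stat=t, df=float(nu_round), p_value=lookup.p_value)


def secure_smd(session: FederatedSession, indicators, attr, mode: str = "revealed"):
    """Secure standardized mean difference (Hedges' g) with variance.

    mode="revealed" returns SecureSMD; mode="shared" keeps (g, var_g)
    secret-shared for downstream meta-analysis."""
    if mode not in ("revealed", "shared"):
        raise ValueError("mode must be 'revealed' or 'shared'")
    if not isinstance(attr, SecureAttribute):
        attr = SecureAttribute.from_parts(session, attr)
    c = _validate_indicators(indicators, attr.n, partition=False)
    if c.shape[0] != 2:
        raise ValueError("SMD needs exactly 2 indicator rows")
    mpc = session.mpc
    b = session.bounds
    n = attr.n
    s_sh, ss_sh, n_sh = _group_aggregates(session, attr, c)
    (m1, m2), _, (e1, e2) = _means_and_variances(session, s_sh, ss_sh, n_sh, n)
    n1, n2 = n_sh
    nn = n1 + n2
    s2p = mpc.div(e1 + e2, nn + (-2.0), bound_pub=2 * n, den_floor=2.0)
    inv_s = mpc.inv_sqrt(s2p, bound_pub=b.var_max, floor_pub=b.var_min)
    # small-sample correction 1 - 3/(4(n1+n2) - 9), on private sizes
    den_j = mpc.mul_pub_int(nn, 4) + (-9.0)
    j = 1.0 - mpc.div(mpc.const(3.0), den_j, bound_pub=8 * n, den_floor=7.0)
    g_sh = mpc.mul(mpc.mul(m1 - m2, inv_s), j)
    term1 = mpc.div(nn, mpc.mul(n1, n2), bound_pub=(n / 2.0) ** 2 + 1, den_floor=4.0)
    term2 = mpc.div(
        mpc.mul(g_sh, g_sh),
        mpc.mul_pub_int(nn, 2) + (-3.94),
        bound_pub=2 * n,
        den_floor=4.0 - 3.94,
    )
    varg_sh = term1 + term2
    if mode == "shared":
        return g_sh, varg_sh
    return SecureSMD(
        g=mpc.reveal(g_sh, "g"), var_g=mpc.reveal(varg_sh, "var_g")
    )


def _reshare(x: SecretShare, target: MpcSession) -> SecretShare:
    """Move a sharing into another session with identical ring parameters:
    each party privately inputs its own share."""
    src = x.session.params
    dst = target.params
    if (src.k, src.f) != (dst.k, dst.f):
        raise ValueError("ring parameters differ; cannot reshare")
    out = None
    for s in x.shares:
        part = target.share_ring(s)
        out = part if out is None else out + part
    return out


@dataclass(frozen=True)
class MetaBounds:
    """Public bounds for meta-analysis quantities: per-study variance of
    Hedges' g (var_g >= (n1+n2)/(n1 n2) bounds weights from above)."""

    varg_max: float = 16.0
    varg_min: float = 1e-3

    @property
    def w_max(self) -> float:
        return 1.0 / self.varg_min


def secure_meta(
    pairs,
    session: MpcSession | None = None,
    bounds: MetaBounds | None = None,
    reveal_weights: bool = False,
) -> MetaResult:
    """Secure fixed/random-effect meta-analysis over R >= 2 cohorts'
    secret-shared (g_r, var_g_r).

    Pools with inverse-variance weights, computes Cochran's Q and the
    DerSimonian-Laird tau^2 (truncated at zero via a secure comparison),
    re-pools with random-effect weights, and reveals only the pooled
    results (per-study weights only when every cohort's policy permits)."""
    pairs = list(pairs)
    r = len(pairs)
    if r < 2:
        raise ProtocolAbort(f"meta-analysis needs >= 2 studies, got {r}")
    b = bounds or MetaBounds()
    if session is None:
        session = pairs[0][0].session
    mpc = session
    gs, vs = [], []
    for g_sh, v_sh in pairs:
        gs.append(g_sh if g_sh.session is mpc else _reshare(g_sh, mpc))
        vs.append(v_sh if v_sh.session is mpc else _reshare(v_sh, mpc))

    def pool(weights):
        sw = weights[0]
        for w in weights[1:]:
            sw = sw + w
        swg = None
        for w, g in zip(weights, gs):
            t = mpc.mul(w, g)
            swg = t if swg is None else swg + t
        ghat = mpc.div(swg, sw, bound_pub=r * b.w_max, den_floor=r / b.varg_max)
        half = mpc.mul_pub(
            mpc.inv_sqrt(sw, bound_pub=r * b.w_max, floor_pub=r / b.varg_max),
            1.96,
        )
        return sw, swg, ghat, half

    w = [mpc.div(mpc.const(1.0), v, bound_pub=b.varg_max, den_floor=b.varg_min)
         for v in vs]
    sw, swg, ghat, half = pool(w)

    # Cochran's Q = sum w g^2 - (sum w g)^2 / sum w
    swg2 = None
    for wi, g in zip(w, gs):
        t = mpc.mul(wi, mpc.mul(g, g))
        swg2 = t if swg2 is None else swg2 + t
    q_sh = swg2 - mpc.div(
        mpc.mul(swg, swg), sw, bound_pub=r * b.w_max, den_floor=r / b.varg_max
    )
    # DL tau^2 = max(0, (Q - (R-1)) / (sum w - sum w^2 / sum w))
    sw2 = None
    for wi in w:
        t = mpc.mul(wi, wi)
        sw2 = t if sw2 is None else sw2 + t
    c_sh = sw - mpc.div(
        sw2, sw, bound_pub=r * b.w_max * b.w_max, den_floor=r / b.varg_max
    )
    tau_raw = mpc.div(
        q_sh + (-(r - 1.0)), c_sh, bound_pub=r * b.w_max,
        den_floor=1.0 / (2.0 * b.varg_max),
    )
    positive = mpc.reveal(mpc.cmp(tau_raw, 0.0), "tau2_positive") >= 0.5
    tau2_sh = tau_raw if positive else mpc.const(0.0)

    w_star = [
        mpc.div(mpc.const(1.0), v + tau2_sh, bound_pub=4 * b.varg_max,
                den_floor=b.varg_min)
        for v in vs
    ]
    sw_s, _, ghat_s, half_s = pool(w_star)

    g_fixed = mpc.reveal(ghat, "g_fixed")
    half_f = mpc.reveal(half, "ci_half_fixed")
    q_stat = mpc.reveal(q_sh, "q_stat")
    tau2 = mpc.reveal(tau2_sh, "tau2") if positive else 0.0
    g_random = mpc.reveal(ghat_s, "g_random")
    half_r = mpc.reveal(half_s, "ci_half_random")

    weights_fixed = weights_random = ()
    if reveal_weights:
        weights_fixed = tuple(
            mpc.reveal(
                mpc.div(wi, sw, bound_pub=r * b.w_max, den_floor=r / b.varg_max),
                f"weight_fixed_{i}",
            )
            for i, wi in enumerate(w)
        )
        weights_random = tuple(
            mpc.reveal(
                mpc.div(wi, sw_s, bound_pub=r * b.w_max, den_floor=r / b.varg_max),
                f"weight_random_{i}",
            )
            for i, wi in enumerate(w_star)
        )
    return MetaResult(
        n_studies=r,
        g_fixed=g_fixed,
        ci_fixed=(g_fixed - half_f, g_fixed + half_f),
        q_stat=q_stat,
        tau2=tau2,
        g_random=g_random,
        ci_random=(g_random - half_r, g_random + half_r),
        weights_fixed=weights_fixed,
        weights_random=weights_random,
    )
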