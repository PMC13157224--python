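"""Plaintext reference statistics.

Every quantity the secure federated protocols compute exists here first in
ordinary NumPy/SciPy form: PGS standardization against the control group,
rank-based quintile assignment, the case/control labelling rule, Welch's
t-test, one-way ANOVA, the bias-corrected standardized mean difference
(Hedges' g) with its variance, and inverse-variance fixed/random-effect
meta-analysis with the DerSimonian-Laird tau^2 estimator.

These functions are the per-cohort preparation layer and the oracle against
which all secure-vs-plaintext agreement checks run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "StandardizationParams",
    "TTestResult",
    "AnovaResult",
    "SMDResult",
    "MetaResult",
    "standardize_scores",
    "assign_quintiles",
    "label_case_control",
    "welch_ttest",
    "one_way_anova",
    "smd_hedges",
    "meta_analyze",
]

# Control-group blood-pressure thresholds (mmHg): a participant is a control
# iff no hypertension history AND sbp < SBP_CUTOFF AND dbp < DBP_CUTOFF.
SBP_CUTOFF = 130.0
DBP_CUTOFF = 85.0


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined for the given data (zero variance,
    empty group, too few observations or studies)."""


@dataclass(frozen=True)
class StandardizationParams:
    """Location/scale of the control group's raw PGS distribution."""

    mu_control: float
    sigma_control: float

    def __post_init__(self) -> None:
        if not (self.sigma_control > 0):
            raise ValueError(
                f"sigma_control must be > 0, got {self.sigma_control}"
            )


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: float  # Welch-Satterthwaite nu
    p_value: float
    n1: int = 0
    n2: int = 0


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class SMDResult:
    """Hedges' g between two groups, with its sampling variance."""

    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    s_pooled: float
    g: float
    var_g: float


@dataclass(frozen=True)
class MetaResult:
    """Fixed- and random-effect inverse-variance pooling of R studies."""

    n_studies: int
    g_fixed: float
    ci_fixed: tuple[float, float]
    q_stat: float
    tau2: float
    g_random: float
    ci_random: tuple[float, float]
    weights_fixed: tuple[float, ...] = field(default=())
    weights_random: tuple[float, ...] = field(default=())


def standardize_scores(scores, params: StandardizationParams) -> np.ndarray:
    """Standardize raw polygenic scores against the control group:
    s_hat_i = (s_i - mu_control) / sigma_control."""
    scores = np.asarray(scores, dtype=float)
    if not (params.sigma_control > 0):
        raise ValueError("sigma_control must be > 0")
    return (scores - params.mu_control) / params.sigma_control


def assign_quintiles(standardized_scores) -> np.ndarray:
    """Rank-based quintile (1..5) per observation.

    Ties share a quintile: a tied block receives the quintile of the
    smallest rank in the block, so the assignment is deterministic and
    permutation-invariant. With n distinct values the group sizes differ
    by at most one.
    """
    x = np.asarray(standardized_scores, dtype=float)
    n = x.size
    if n < 5:
        raise DegenerateDataError(
            f"need at least 5 observations for quintiles, got {n}"
        )
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    # min rank within each tied block
    min_rank: dict[float, int] = {}
    for r, v in zip(ranks, x):
        if v not in min_rank or r < min_rank[v]:
            min_rank[v] = int(r)
    eff = np.array([min_rank[v] for v in x], dtype=np.int64)
    q = np.ceil(5.0 * eff / n).astype(np.int64)
    return np.clip(q, 1, 5)


def label_case_control(sbp, dbp, htn_history) -> str:
    """Apply the case/control rule to one participant.

    control iff no hypertension history AND sbp < 130 mmHg AND dbp < 85 mmHg;
    case otherwise.
    """
    for name, v in (("sbp", sbp), ("dbp", dbp), ("htn_history", htn_history)):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"missing required field: {name}")
    if (not htn_history) and sbp < SBP_CUTOFF and dbp < DBP_CUTOFF:
        return "control"
    return "case"


def welch_ttest(x1, x2) -> TTestResult:
    """Welch's two-sample t-test (unequal variances), two-sided p."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise DegenerateDataError("each group needs at least 2 observations")
    v1 = x1.var(ddof=1)
    v2 = x2.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise DegenerateDataError("both groups have zero variance")
    res = sps.ttest_ind(x1, x2, equal_var=False)
    return TTestResult(
        t_stat=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        n1=n1,
        n2=n2,
    )


def one_way_anova(x, groups, n_groups: int | None = None) -> AnovaResult:
    """One-way fixed-effects ANOVA; F = MSB/MSW, upper-tail p from
    F(K-1, N-K)."""
    x = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if n_groups is not None and labels.size != n_groups:
        raise DegenerateDataError(
            f"expected {n_groups} nonempty groups, found {labels.size}"
        )
    samples = [x[groups == lab] for lab in labels]
    k = len(samples)
    n_total = x.size
    if k < 2 or any(s.size == 0 for s in samples):
        raise DegenerateDataError("need >= 2 nonempty groups")
    if n_total <= k:
        raise DegenerateDataError("need N > K")
    f_stat, p = sps.f_oneway(*samples)
    return AnovaResult(
        f_stat=float(f_stat),
        df_between=k - 1,
        df_within=n_total - k,
        p_value=float(p),
    )


def smd_hedges(x1, x2) -> SMDResult:
    """Bias-corrected standardized mean difference (Hedges' g).

    With pooled sd  s = sqrt((s1^2 (n1-1) + s2^2 (n2-1)) / (n1+n2-2)):

        g     = (xbar1 - xbar2)/s * (1 - 3/(4(n1+n2) - 9))
        var_g = (n1+n2)/(n1*n2) + g^2/(2(n1+n2) - 3.94)
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise DegenerateDataError("each group needs at least 2 observations")
    m1, m2 = x1.mean(), x2.mean()
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    pooled = (v1 * (n1 - 1) + v2 * (n2 - 1)) / (n1 + n2 - 2)
    if pooled <= 0:
        raise DegenerateDataError("zero pooled variance")
    s = float(np.sqrt(pooled))
    correction = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    g = (m1 - m2) / s * correction
    var_g = (n1 + n2) / (n1 * n2) + g * g / (2.0 * (n1 + n2) - 3.94)
    return SMDResult(
        n1=n1, n2=n2,
        mean1=float(m1), mean2=float(m2),
        sd1=float(np.sqrt(v1)), sd2=float(np.sqrt(v2)),
        s_pooled=s, g=float(g), var_g=float(var_g),
    )


def meta_analyze(studies) -> MetaResult:
    """Inverse-variance meta-analysis of per-study (g, var_g) pairs.

    Fixed effect: w_r = 1/var_g_r, ghat = sum(w g)/sum(w),
    95% CI = ghat +/- 1.96/sqrt(sum w).  Heterogeneity via Cochran's Q;
    DerSimonian-Laird tau^2 = max(0, (Q - (R-1)) / (sum w - sum w^2/sum w)),
    truncated at zero.  Random effect re-pools with w*_r = 1/(var_g_r + tau^2).
    """
    gs = np.array([g for g, _ in studies], dtype=float)
    vs = np.array([v for _, v in studies], dtype=float)
    r = gs.size
    if r < 2:
        raise DegenerateDataError(f"need >= 2 studies, got {r}")
    if np.any(vs <= 0):
        raise ValueError("all study variances must be > 0")

    w = 1.0 / vs
    sw = w.sum()
    g_fixed = float((w * gs).sum() / sw)
    half = 1.96 / np.sqrt(sw)
    ci_fixed = (g_fixed - half, g_fixed + half)

    q = float((w * gs * gs).sum() - ((w * gs).sum()) ** 2 / sw)
    denom = sw - (w * w).sum() / sw
    tau2 = max(0.0, (q - (r - 1)) / denom)

    w_star = 1.0 / (vs + tau2)
    sw_star = w_star.sum()
    g_random = float((w_star * gs).sum() / sw_star)
    half_star = 1.96 / np.sqrt(sw_star)
    ci_random = (g_random - half_star, g_random + half_star)

    return MetaResult(
        n_studies=r,
        g_fixed=g_fixed,
        ci_fixed=(float(ci_fixed[0]), float(ci_fixed[1])),
        q_stat=q,
        tau2=float(tau2),
        g_random=g_random,
        ci_random=(float(ci_random[0]), float(ci_random[1])),
        weights_fixed=tuple(float(x) for x in w / sw),
        weights_random=tuple(float(x) for x in w_star / sw_star),
    )
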