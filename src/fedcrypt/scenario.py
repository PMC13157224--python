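"""End-to-end study scenario over two synthetic cohorts.

Mirrors the PGS-evaluation workflow: per cohort, the genomic and phenotype
sites link records with PSI; the genomic site groups participants by
polygenic-score quintile (quintile membership is invariant to the
control-group standardization, which is monotone); then, per case/control
x sex stratum, the sites run a secure five-group ANOVA and secure Welch
t-tests comparing the fifth-vs-first and fifth-vs-third quintiles; per sex,
the case strata additionally run a secure Q5-vs-Q1 SMD whose secret-shared
(g, var_g) feed a cross-cohort fixed/random-effect meta-analysis.

Every secure result is accompanied by the plaintext-oracle value computed
on the same linked data, and the report carries per-statistic relative
agreement; the scenario's headline number is the minimum agreement across
all revealed statistics.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np

from fedcrypt import stat_core as sc
from fedcrypt.mpc.lookup import grid_for
from fedcrypt.protocols import (
    AttributeBounds,
    FederatedSession,
    ProtocolAbort,
    SecureAttribute,
    secure_anova,
    secure_meta,
    secure_smd,
    secure_ttest,
)
from fedcrypt.psi import IdSet, psi_intersect
from fedcrypt.synth import SimConfig, generate_cohort, label_phenotypes
from fedcrypt.transcript import Transcript

__all__ = ["ScenarioConfig", "run_study_scenario", "relative_agreement"]


@dataclass(frozen=True)
class ScenarioConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    cohort_shift: float = 12.0       # second cohort's extra SBP (mmHg)
    cohort_history_factor: float = 3.0
    smd_label: str = "case"          # stratum label feeding SMD/meta
    psi_group_bits: int = 256        # demo-grade group for in-process runs
    reveal_weights: bool = False
    bounds: AttributeBounds = field(default_factory=AttributeBounds)
    seed: int = 0


def relative_agreement(secure: float, plain: float) -> float:
    """100 * (1 - |secure-plain|/|plain|); an exactly-zero oracle value is
    scored as exact agreement only when the secure value matches to 1e-9."""
    d = abs(secure - plain)
    if abs(plain) < 1e-12:
        return 100.0 if d <= 1e-9 else 0.0
    return 100.0 * (1.0 - d / abs(plain))


def _prepare_cohort(cfg: ScenarioConfig, cohort_id: str, shift: float, hist_factor: float):
    sim = replace(
        cfg.sim,
        seed=cfg.seed,
        cohort_health_shift=cfg.sim.cohort_health_shift + shift,
        history_rate=min(1.0, cfg.sim.history_rate * hist_factor),
    )
    return generate_cohort(sim, cohort_id)


def _standardization(scores: np.ndarray, labels: np.ndarray) -> sc.StandardizationParams:
    ctrl = scores[labels == "control"]
    if ctrl.size < 2 or ctrl.std(ddof=1) == 0:
        raise ProtocolAbort("control group too small to standardize against")
    return sc.StandardizationParams(float(ctrl.mean()), float(ctrl.std(ddof=1)))


def run_study_scenario(
    config: ScenarioConfig | None = None,
    seed: int | None = None,
    return_artifacts: bool = False,
):
    """Run the full two-cohort secure study; returns the JSON-able report
    (and, optionally, transcripts plus sensitive intermediates for audit)."""
    cfg = config or ScenarioConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)

    report: dict = {
        "provenance": {
            "seed": cfg.seed,
            "backend": "reference",
            "psi_group_bits": cfg.psi_group_bits,
            "bounds": asdict(cfg.bounds),
            "sim": asdict(cfg.sim),
        },
        "cohorts": [],
        "analyses": [],
        "meta_analyses": [],
        "aborts": [],
    }
    artifacts = {"transcripts": [], "sensitive": [], "identifiers": []}
    agreements: list[float] = []
    shared_smd: dict[str, list] = {}   # sex -> [(g_sh, varg_sh), ...]
    plain_smd: dict[str, list] = {}    # sex -> [(g, var_g), ...]
    meta_ring = None

    cohort_specs = [
        ("cohortA", 0.0, 1.0),
        ("cohortB", cfg.cohort_shift, cfg.cohort_history_factor),
    ]
    for ci, (cohort_id, shift, hf) in enumerate(cohort_specs):
        genomic, phenotype = _prepare_cohort(cfg, cohort_id, shift, hf)
        psi_transcript = Transcript(f"{cohort_id}:psi")
        linkage = psi_intersect(
            IdSet(tuple(genomic["id"]), "genomic"),
            IdSet(tuple(phenotype["id"]), "phenotype"),
            group_bits=cfg.psi_group_bits,
            seed=cfg.seed * 1000 + ci,
            transcript=psi_transcript,
        )
        if linkage.n_common < 25:
            report["aborts"].append(
                {"cohort": cohort_id, "reason": "PSI intersection too small"}
            )
            continue
        g_rows = genomic.iloc[linkage.row_index["genomic"]].reset_index(drop=True)
        p_rows = phenotype.iloc[linkage.row_index["phenotype"]].reset_index(drop=True)
        scores = g_rows["pgs_score1"].to_numpy()
        labels = label_phenotypes(p_rows).to_numpy()
        params = _standardization(scores, labels)
        std_scores = sc.standardize_scores(scores, params)
        quintile = sc.assign_quintiles(std_scores)  # genomic-site grouping
        sbp = p_rows["sbp"].to_numpy()
        sexes = p_rows["sex"].to_numpy()

        report["cohorts"].append(
            {
                "id": cohort_id,
                "n_genomic": int(len(genomic)),
                "n_phenotype": int(len(phenotype)),
                "n_common": int(linkage.n_common),
            }
        )
        artifacts["transcripts"].append(psi_transcript)
        artifacts["identifiers"].extend(genomic["id"].tolist())
        artifacts["identifiers"].extend(phenotype["id"].tolist())

        session = FederatedSession(
            seed=cfg.seed * 7919 + ci, bounds=cfg.bounds, session_id=cohort_id
        )
        meta_ring = session.mpc.params
        artifacts["transcripts"].append(session.transcript)

        for label in ("case", "control"):
            for sex in ("female", "male"):
                mask = (labels == label) & (sexes == sex)
                stratum = {"cohort": cohort_id, "label": label, "sex": sex,
                           "n": int(mask.sum())}
                x = sbp[mask]
                q = quintile[mask]
                sizes = np.array([(q == k).sum() for k in range(1, 6)])
                if (sizes < 2).any() or x.size <= 5:
                    report["aborts"].append(
                        {**stratum, "reason": f"quintile sizes {sizes.tolist()}"}
                    )
                    continue
                artifacts["sensitive"].extend(_sensitive_sums(x, q))
                attr = SecureAttribute.from_parts(session, [x])
                indicators = np.stack([(q == k).astype(int) for k in range(1, 6)])

                _run_anova(session, indicators, attr, x, q, stratum,
                           report, agreements)
                for hi, lo, tag in ((5, 1, "ttest_q5_q1"), (5, 3, "ttest_q5_q3")):
                    _run_ttest(session, attr, x, q, hi, lo, tag, stratum,
                               report, agreements)

                if label == cfg.smd_label:
                    _run_smd(session, attr, x, q, stratum, report, agreements,
                             shared_smd, plain_smd, artifacts)

    for sex, pairs in sorted(shared_smd.items()):
        if len(pairs) < 2:
            report["aborts"].append(
                {"analysis": "meta", "sex": sex,
                 "reason": f"only {len(pairs)} cohort(s) produced an SMD"}
            )
            continue
        from fedcrypt.mpc.engine import MpcSession

        meta_transcript = Transcript(f"meta:{sex}")
        sex_offset = {"female": 1, "male": 2}.get(sex, 3)
        meta_mpc = MpcSession(
            meta_ring, seed=cfg.seed * 104729 + sex_offset,
            transcript=meta_transcript, session_id=f"meta:{sex}",
        )
        secure = secure_meta(
            pairs, session=meta_mpc, reveal_weights=cfg.reveal_weights
        )
        plain = sc.meta_analyze(plain_smd[sex])
        agreement = {
            "g_fixed": relative_agreement(secure.g_fixed, plain.g_fixed),
            "g_random": relative_agreement(secure.g_random, plain.g_random),
            "tau2": relative_agreement(secure.tau2, plain.tau2),
            "ci_fixed_lo": relative_agreement(secure.ci_fixed[0], plain.ci_fixed[0]),
            "ci_fixed_hi": relative_agreement(secure.ci_fixed[1], plain.ci_fixed[1]),
            "ci_random_lo": relative_agreement(secure.ci_random[0], plain.ci_random[0]),
            "ci_random_hi": relative_agreement(secure.ci_random[1], plain.ci_random[1]),
        }
        agreements.extend(agreement.values())
        report["meta_analyses"].append(
            {
                "sex": sex,
                "secure": asdict(secure),
                "plaintext": asdict(plain),
                "agreement": agreement,
            }
        )
        artifacts["transcripts"].append(meta_transcript)

    report["agreement_min"] = min(agreements) if agreements else float("nan")
    report["agreement_count"] = len(agreements)
    if return_artifacts:
        return report, artifacts
    return report


def _sensitive_sums(x: np.ndarray, q: np.ndarray) -> list[float]:
    out = []
    for k in range(1, 6):
        xk = x[q == k]
        if xk.size:
            out.extend([float(xk.sum()), float((xk * xk).sum()), float(xk.mean())])
    return out


def _run_anova(session, indicators, attr, x, q, stratum, report, agreements):
    try:
        secure = secure_anova(session, indicators, attr)
    except ProtocolAbort as exc:
        report["aborts"].append({**stratum, "test": "anova", "reason": str(exc)})
        return
    plain = sc.one_way_anova(x, q)
    agreement = {"f_stat": relative_agreement(secure.f_stat, plain.f_stat)}
    agreements.extend(agreement.values())
    grid = grid_for(plain.df_between, plain.df_within)
    report["analyses"].append(
        {
            **stratum,
            "test": "anova",
            "secure": asdict(secure),
            "plaintext": asdict(plain),
            "agreement": agreement,
            "p_match": secure.p_value == grid.nearest_p(plain.p_value),
        }
    )


def _run_ttest(session, attr, x, q, hi, lo, tag, stratum, report, agreements):
    ind = np.stack([(q == hi).astype(int), (q == lo).astype(int)])
    try:
        secure = secure_ttest(session, ind, attr)
    except ProtocolAbort as exc:
        report["aborts"].append({**stratum, "test": tag, "reason": str(exc)})
        return
    plain = sc.welch_ttest(x[q == hi], x[q == lo])
    agreement = {"t_stat": relative_agreement(secure.t_stat, plain.t_stat)}
    agreements.extend(agreement.values())
    grid = grid_for(1, int(min(max(round(plain.df), 1), 200)))
    report["analyses"].append(
        {
            **stratum,
            "test": tag,
            "secure": asdict(secure),
            "plaintext": asdict(plain),
            "agreement": agreement,
            "p_match": secure.p_value == grid.nearest_p(plain.p_value),
        }
    )


def _run_smd(session, attr, x, q, stratum, report, agreements,
             shared_smd, plain_smd, artifacts):
    ind = np.stack([(q == 5).astype(int), (q == 1).astype(int)])
    try:
        revealed = secure_smd(session, ind, attr, mode="revealed")
        pair = secure_smd(session, ind, attr, mode="shared")
    except ProtocolAbort as exc:
        report["aborts"].append({**stratum, "test": "smd_q5_q1", "reason": str(exc)})
        return
    plain = sc.smd_hedges(x[q == 5], x[q == 1])
    agreement = {
        "g": relative_agreement(revealed.g, plain.g),
        "var_g": relative_agreement(revealed.var_g, plain.var_g),
    }
    agreements.extend(agreement.values())
    report["analyses"].append(
        {
            **stratum,
            "test": "smd_q5_q1",
            "secure": asdict(revealed),
            "plaintext": asdict(plain),
            "agreement": agreement,
        }
    )
    sex = stratum["sex"]
    shared_smd.setdefault(sex, []).append(pair)
    plain_smd.setdefault(sex, []).append((plain.g, plain.var_g))
    artifacts["sensitive"].append(plain.g)
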