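"""Synthetic two-cohort generator.

Emulates the study layout the federated protocols assume: each cohort has a
genomic site (participant id, polygenic score) and a phenotype site
(participant id, sex, systolic/diastolic blood pressure, hypertension
history), vertically partitioned with configurable incomplete overlap so
that record linkage is actually exercised. Systolic pressure follows a
linear-in-quintile-rank effect of the standardized polygenic score plus a
sex effect, a per-cohort health shift and Gaussian noise; the case/control
label is always derived afterwards by the labelling rule, never generated
directly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from fedcrypt.stat_core import assign_quintiles, label_case_control

__all__ = ["SimConfig", "generate_cohort", "generate_pair", "inject_true_smd"]


@dataclass(frozen=True)
class SimConfig:
    """Cohort simulation parameters (blood pressures in mmHg)."""

    n_per_cohort: int = 1000
    prob_male: float = 0.5
    quintile_effect: float = 3.0      # SBP change per quintile step
    sex_effect: float = 4.0           # SBP shift for males
    sbp_base: float = 118.0
    sbp_noise_sd: float = 12.0
    dbp_base: float = 76.0
    dbp_quintile_effect: float = 1.0
    dbp_sex_effect: float = 2.0
    dbp_noise_sd: float = 8.0
    history_rate: float = 0.12
    cohort_health_shift: float = 0.0  # e.g. +10 for a cardiovascular cohort
    site_overlap: float = 0.95        # fraction of ids present at BOTH sites
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prob_male", "history_rate", "site_overlap"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sbp_noise_sd <= 0 or self.dbp_noise_sd <= 0:
            raise ValueError("noise sds must be positive")


def _rng_for(config: SimConfig, cohort_id: str) -> np.random.Generator:
    h = hashlib.sha256(f"synth:{config.seed}:{cohort_id}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:8], "big"))


def generate_cohort(
    config: SimConfig, cohort_id: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One cohort as (genomic table, phenotype table).

    The tables share participant ids up to the configured site overlap:
    each site independently misses a disjoint slice of participants, so
    the intersection is ~site_overlap * n.
    """
    n = config.n_per_cohort
    if n < 25:
        raise ValueError(f"need n >= 25 for quintile structure, got {n}")
    rng = _rng_for(config, cohort_id)

    ids = np.array([f"{cohort_id}-P{i:06d}" for i in range(n)])
    pgs = rng.normal(0.0, 1.0, n)
    quintile = assign_quintiles(pgs)
    male = rng.random(n) < config.prob_male
    sex = np.where(male, "male", "female")

    sbp = (
        config.sbp_base
        + config.cohort_health_shift
        + config.quintile_effect * (quintile - 3)
        + config.sex_effect * male
        + rng.normal(0.0, config.sbp_noise_sd, n)
    )
    dbp = (
        config.dbp_base
        + 0.5 * config.cohort_health_shift
        + config.dbp_quintile_effect * (quintile - 3)
        + config.dbp_sex_effect * male
        + rng.normal(0.0, config.dbp_noise_sd, n)
    )
    history = rng.random(n) < config.history_rate

    genomic = pd.DataFrame({"id": ids, "pgs_score1": pgs})
    phenotype = pd.DataFrame(
        {
            "id": ids,
            "sex": sex,
            "sbp": np.round(sbp, 4),
            "dbp": np.round(dbp, 4),
            "htn_history": history,
        }
    )

    # disjoint dropouts at the two sites
    n_drop = int(round((1.0 - config.site_overlap) * n / 2.0))
    if n_drop > 0:
        dropped = rng.choice(n, size=2 * n_drop, replace=False)
        genomic = genomic.drop(index=dropped[:n_drop]).reset_index(drop=True)
        phenotype = phenotype.drop(index=dropped[n_drop:]).reset_index(drop=True)
    return genomic, phenotype


def generate_pair(config: SimConfig, shift_second: float = 12.0):
    """Two cohorts: a healthy-volunteer-like cohort and a cardiovascular
    cohort shifted toward higher pressures and history rates."""
    c1 = config
    c2 = replace(
        config,
        cohort_health_shift=config.cohort_health_shift + shift_second,
        history_rate=min(1.0, config.history_rate * 3.0),
    )
    return generate_cohort(c1, "cohortA"), generate_cohort(c2, "cohortB")


def label_phenotypes(phenotype: pd.DataFrame) -> pd.Series:
    """Case/control per participant, via the labelling rule."""
    return phenotype.apply(
        lambda r: label_case_control(r["sbp"], r["dbp"], bool(r["htn_history"])),
        axis=1,
    )


def inject_true_smd(config: SimConfig, target_d: float) -> SimConfig:
    """Set the quintile effect so the population SMD in SBP between the
    top and bottom quintile equals target_d: four quintile steps of
    target_d * sbp_noise_sd / 4 each."""
    if target_d < 0:
        raise ValueError("target_d must be >= 0")
    return replace(config, quintile_effect=target_d * config.sbp_noise_sd / 4.0)
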