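"""Seeded generator of synthetic post-transplant cohorts.

The generator is artifact plumbing, not a physiological model: it produces
minimal dynamics that make the trajectory features informative.  A latent
severity (standard-normal noise plus standardized MELD and cold-ischemia
contributions) shifts the level/trend of every log-lab trajectory and drives
the 90-day failure probability through a logistic link, so that score
discrimination against outcome can be switched on, off, or scaled.

Trajectory shapes: ln AST/ALT decline from a post-reperfusion peak; the
bilirubin trend sign is tied to severity (recovery vs cholestasis); platelets
dip then recover; INR sits near 1 with severity-scaled elevation.  Lab values
are lognormal, hence always positive.  PODs 8-10 can be missing (same days
for all analytes, echoing sparse late sampling), and deaths before POD 10
truncate the lab series, which is what produces the "insufficient labs"
exclusions downstream.

Reproducibility: patient ``i`` uses the dedicated stream
``default_rng([seed, i])``, so cohorts are identical for a given (config,
seed) and stable under changes of ``n``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .cohort import ClinicalRecord, Cohort, LabSeries, OutcomeRecord


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass
class SyntheticConfig:
    """Generator knobs; defaults give ~20% high-risk patients and a ~9%
    90-day failure rate."""

    n: int = 500
    seed: int = 0

    # latent severity = N(0,1) + meld_effect*z(MELD) + cit_effect*z(CIT)
    meld_effect: float = 0.35
    cit_effect: float = 0.30

    # ln AST = ast_level + ast_level_sev*sev + (ast_trend + ast_trend_sev*sev)*(pod-1)
    ast_level: float = 6.5
    ast_level_sev: float = 0.75
    ast_trend: float = -0.35
    ast_trend_sev: float = 0.12
    alt_level: float = 6.0
    alt_level_sev: float = 0.50
    alt_trend: float = -0.28
    alt_trend_sev: float = 0.07
    tbil_level: float = 0.8
    tbil_level_sev: float = 0.7
    tbil_trend: float = -0.10
    tbil_trend_sev: float = 0.20
    inr_level: float = 0.18
    inr_level_sev: float = 0.25
    inr_trend: float = -0.02
    inr_trend_sev: float = 0.01
    plt_level: float = 4.2
    plt_level_sev: float = -0.4
    plt_trend: float = 0.05
    plt_trend_sev: float = -0.03
    noise_sd: float = 0.12

    # outcome: P(failure by day 90) = expit(intercept + coef*severity);
    # event time exponential with the matching rate, censoring independent
    outcome_intercept: float = -3.0
    outcome_coef: float = 1.4
    retransplant_fraction: float = 0.2
    censor_min_days: float = 200.0
    censor_max_days: float = 1200.0

    # probability each of PODs 8-10 is unobserved (all analytes together)
    pod8_10_missing: float = 0.08

    # covariate / flag prevalences
    thrombosis_prevalence: float = 0.05
    center_volume_ge70_prob: float = 0.5
    exclusion_flag_prevalence: float = 0.015

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name in (
            "pod8_10_missing",
            "thrombosis_prevalence",
            "center_volume_ge70_prob",
            "exclusion_flag_prevalence",
            "retransplant_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.censor_max_days < self.censor_min_days:
            raise ValueError("censor_max_days < censor_min_days")

    def to_dict(self) -> dict:
        return asdict(self)


_TRAJ_PARAMS = {
    "AST": ("ast_level", "ast_level_sev", "ast_trend", "ast_trend_sev"),
    "ALT": ("alt_level", "alt_level_sev", "alt_trend", "alt_trend_sev"),
    "TBIL": ("tbil_level", "tbil_level_sev", "tbil_trend", "tbil_trend_sev"),
    "INR": ("inr_level", "inr_level_sev", "inr_trend", "inr_trend_sev"),
    "PLT": ("plt_level", "plt_level_sev", "plt_trend", "plt_trend_sev"),
}

_EXCLUSION_FLAGS = (
    "excl_age_lt18",
    "excl_acute_liver_failure",
    "excl_retransplant",
    "excl_multivisceral",
    "excl_split",
    "excl_living_donor",
    "excl_early_vascular",
)


def _generate_patient(config: SyntheticConfig, index: int):
    rng = np.random.default_rng([config.seed, index])
    pid = f"P{index:05d}"

    meld = float(min(40, 6 + round(rng.gamma(2.0, 4.0))))
    cit = float(max(60.0, rng.normal(420.0, 90.0)))
    severity = float(
        rng.normal()
        + config.meld_effect * (meld - 14.0) / 8.0
        + config.cit_effect * (cit - 420.0) / 90.0
    )

    clin = ClinicalRecord(
        patient_id=pid,
        recipient_age=float(np.clip(round(rng.normal(50, 10)), 18, 75)),
        recipient_male=bool(rng.random() < 0.85),
        recipient_bmi=float(np.round(rng.normal(23.0, 3.0), 1)),
        diagnosis=str(rng.choice(["HCC", "HBV_cirrhosis", "ACLF", "alcoholic", "other"],
                                 p=[0.53, 0.22, 0.10, 0.04, 0.11])),
        meld=meld,
        preop_tbil_umol_l=float(np.round(np.exp(rng.normal(3.7, 1.0) + 0.3 * severity), 1)),
        preop_inr=float(np.round(np.exp(rng.normal(0.3, 0.25) + 0.05 * severity), 2)),
        preop_crea_umol_l=float(np.round(np.exp(rng.normal(4.27, 0.3)), 0)),
        child_pugh=float(np.clip(round(rng.normal(8, 2)), 5, 15)),
        donor_age=float(np.clip(round(rng.normal(38, 12)), 10, 75)),
        donor_male=bool(rng.random() < 0.75),
        donor_bmi=float(np.round(rng.normal(22.0, 2.5), 1)),
        cause_of_death=str(rng.choice(["trauma", "CVA", "HIE", "other"],
                                      p=[0.48, 0.37, 0.08, 0.07])),
        donation_category=str(rng.choice(["DBD", "DCD", "DBCD"], p=[0.79, 0.16, 0.05])),
        dri=float(np.round(np.exp(rng.normal(0.5, 0.2)), 2)),
        anhepatic_min=float(max(25.0, round(rng.normal(55, 12)))),
        cit_min=cit,
        operation_min=float(max(180.0, round(rng.normal(455, 80)))),
        rbc_units=float(rng.poisson(5)),
        ffp_units=float(rng.poisson(8)),
        hemorrhage_ml=float(max(100.0, round(rng.normal(1800, 900), -1))),
        thrombosis_days_1_10=bool(rng.random() < config.thrombosis_prevalence),
        center_volume_ge70=bool(rng.random() < config.center_volume_ge70_prob),
        **{flag: bool(rng.random() < config.exclusion_flag_prevalence)
           for flag in _EXCLUSION_FLAGS},
    )

    # outcome: exponential event time whose 90-day CDF equals the logistic link
    p90 = _expit(config.outcome_intercept + config.outcome_coef * severity)
    rate = -math.log(max(1e-12, 1.0 - p90)) / 90.0
    event_time = float(rng.exponential(1.0 / rate)) if rate > 0 else math.inf
    censor_time = float(rng.uniform(config.censor_min_days, config.censor_max_days))
    death = retransplant = False
    death_day = retransplant_day = None
    if event_time <= censor_time:
        day = max(1.0, round(event_time, 1))
        if rng.random() < config.retransplant_fraction:
            retransplant, retransplant_day = True, day
            follow_up = censor_time
        else:
            death, death_day = True, day
            follow_up = day
    else:
        follow_up = censor_time
    outcome = OutcomeRecord(
        patient_id=pid,
        follow_up_days=round(follow_up, 1),
        death=death,
        death_day=death_day,
        retransplant=retransplant,
        retransplant_day=retransplant_day,
    )

    # lab trajectories, truncated at death when it precedes POD 10
    labs = LabSeries(patient_id=pid)
    missing_late = {pod: rng.random() < config.pod8_10_missing for pod in (8, 9, 10)}
    last_pod = 10
    if death and death_day is not None and death_day < 10:
        last_pod = int(death_day)
    for analyte, (lvl, lvl_sev, trend, trend_sev) in _TRAJ_PARAMS.items():
        level = getattr(config, lvl) + getattr(config, lvl_sev) * severity
        slope = getattr(config, trend) + getattr(config, trend_sev) * severity
        for pod in range(1, last_pod + 1):
            if pod >= 8 and missing_late[pod]:
                continue
            ln_value = level + slope * (pod - 1) + rng.normal(0.0, config.noise_sd)
            labs.add(analyte, pod, float(np.exp(ln_value)))
    return labs, clin, outcome, severity


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Deterministic synthetic cohort of ``config.n`` patients."""
    labs: dict[str, LabSeries] = {}
    clinical: dict[str, ClinicalRecord] = {}
    outcomes: dict[str, OutcomeRecord] = {}
    for i in range(config.n):
        lab, clin, outcome, _ = _generate_patient(config, i)
        labs[lab.patient_id] = lab
        clinical[clin.patient_id] = clin
        outcomes[outcome.patient_id] = outcome
    return Cohort(labs=labs, clinical=clinical, outcomes=outcomes)


# ---------------------------------------------------------------------------
# hand-constructed regression fixtures


@dataclass(frozen=True)
class KnownAnswer:
    name: str
    labs: LabSeries
    clinical: ClinicalRecord
    expected: dict


def _labs_from(pid: str, table: dict[str, dict[int, float]]) -> LabSeries:
    labs = LabSeries(patient_id=pid)
    for analyte, by_pod in table.items():
        for pod, value in by_pod.items():
            labs.add(analyte, pod, value)
    return labs


def generate_known_answer_set() -> dict[str, KnownAnswer]:
    """Fixture patients whose scores are known in closed form.

    * ``meaf-midpoint`` — every sigmoid at its log-midpoint, total 4.99;
    * ``ead-boundary`` — positive through the bilirubin criterion only;
    * ``lgraft7-intercept`` — all polynomial terms vanish, score 6.9647;
    * ``lgraft10-intercept`` — same for the 10-day score, 9.77.
    """
    e = math.e
    fixtures: dict[str, KnownAnswer] = {}

    labs = _labs_from(
        "KA-MEAF",
        {
            "ALT": {1: e**6.1723 / 2, 2: e**6.1723, 3: e**6.1723 / 2},
            "INR": {1: e**0.6658, 2: e**0.6658 / 2, 3: e**0.6658 / 2},
            "TBIL": {3: e**1.0607},
        },
    )
    fixtures["meaf-midpoint"] = KnownAnswer(
        "meaf-midpoint",
        labs,
        ClinicalRecord(patient_id="KA-MEAF", meld=12, rbc_units=0),
        {"meaf": 3.29 / 2 + 3.29 / 2 + 3.4 / 2, "meaf_group": 2},
    )

    labs = _labs_from(
        "KA-EAD",
        {
            "TBIL": {7: 10.0},
            "INR": {7: 1.2},
            "ALT": {1: 500.0, 4: 300.0},
            "AST": {1: 800.0, 4: 400.0},
        },
    )
    fixtures["ead-boundary"] = KnownAnswer(
        "ead-boundary",
        labs,
        ClinicalRecord(patient_id="KA-EAD"),
        {"ead": True, "criteria": (True, False, False)},
    )

    labs = _labs_from(
        "KA-LG7",
        {
            "AST": {p: 1.0 for p in range(1, 8)},
            "TBIL": {p: 1.0 for p in range(1, 8)},
            "PLT": {p: 1.0 for p in range(1, 8)},
            "INR": {p: 1.0 / 6.0 for p in range(1, 8)},  # raw AUC over span 6 = 1
            "ALT": {p: 1.0 for p in range(1, 8)},
        },
    )
    fixtures["lgraft7-intercept"] = KnownAnswer(
        "lgraft7-intercept",
        labs,
        ClinicalRecord(patient_id="KA-LG7"),
        {"lgraft7": 6.9647, "lgraft7_group": 7, "lgraft7_high": True},
    )

    labs = _labs_from(
        "KA-LG10",
        {analyte: {p: 1.0 for p in range(1, 11)} for analyte in ("AST", "TBIL", "PLT", "INR", "ALT")},
    )
    fixtures["lgraft10-intercept"] = KnownAnswer(
        "lgraft10-intercept",
        labs,
        ClinicalRecord(patient_id="KA-LG10"),
        {"lgraft10": 9.77, "lgraft10_group": 5},
    )
    return fixtures
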