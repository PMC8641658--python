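"""The five early-allograft-function scoring systems and their risk bins.

All published coefficients are evaluated in double precision with no internal
rounding; the only rounding is the 2-decimal rule used before binning the
simplified-estimation (EASE) score, whose printed bin bounds are 2-dp values
with 0.01-wide gaps between consecutive bins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .cohort import ClinicalRecord, LabSeries
from .errors import InsufficientLabs
from . import features as ft

# ---------------------------------------------------------------------------
# dichotomous early-dysfunction criteria


@dataclass(frozen=True)
class EadResult:
    positive: bool
    bilirubin_ge_10: bool       # POD-7 TBIL >= 10 mg/dL
    inr_ge_1_6: bool            # POD-7 INR >= 1.6
    transaminase_gt_2000: bool  # ALT or AST > 2000 IU/L on PODs 1-7 (strict)


def classify_ead(labs: LabSeries) -> EadResult:
    """Dichotomous early-dysfunction call: positive iff >=1 criterion met.

    Boundary semantics exactly as published: >= for the POD-7 bilirubin and
    INR thresholds, strictly > for the transaminase peak.
    """
    inputs = ft.ead_inputs(labs)
    c1 = inputs.tbil_pod7 >= 10.0
    c2 = inputs.inr_pod7 >= 1.6
    c3 = inputs.alt_max_7 > 2000.0 or inputs.ast_max_7 > 2000.0
    return EadResult(c1 or c2 or c3, c1, c2, c3)


# ---------------------------------------------------------------------------
# 3-day sigmoid-sum score (MEAF)

# (amplitude, steepness, log-midpoint) per component
MEAF_ALT_PARAMS = (3.29, 1.9132, 6.1723)
MEAF_INR_PARAMS = (3.29, 6.8204, 0.6658)
MEAF_TBIL_PARAMS = (3.4, 1.8005, 1.0607)

#: supremum of the total score: sum of the three amplitudes
MEAF_MAX = MEAF_ALT_PARAMS[0] + MEAF_INR_PARAMS[0] + MEAF_TBIL_PARAMS[0]


def meaf_component(value: float, params: tuple[float, float, float]) -> float:
    """amplitude / (1 + exp(-steepness * (ln(value) - midpoint)))."""
    amplitude, steepness, midpoint = params
    if value <= 0:
        raise ValueError(f"sigmoid input must be positive, got {value}")
    z = -steepness * (math.log(value) - midpoint)
    if z > 700.0:  # exp would overflow; component limit is 0
        return 0.0
    return amplitude / (1.0 + math.exp(z))


@dataclass(frozen=True)
class MeafResult:
    score: float
    alt_component: float
    inr_component: float
    bilirubin_component: float
    risk_group: int


def meaf_score(inputs: ft.MeafInputs) -> MeafResult:
    alt_c = meaf_component(inputs.alt_max_3pod, MEAF_ALT_PARAMS)
    inr_c = meaf_component(inputs.inr_max_3pod, MEAF_INR_PARAMS)
    bil_c = meaf_component(inputs.bilirubin_pod3, MEAF_TBIL_PARAMS)
    score = alt_c + inr_c + bil_c
    return MeafResult(score, alt_c, inr_c, bil_c, assign_risk_group(score, "meaf").group)


# ---------------------------------------------------------------------------
# L-GrAFT linear predictors (printed polynomial coefficients)


def lgraft7_linear_predictor(
    auc_ln_ast: float,
    slope_ln_ast: float,
    auc_inr: float,
    auc_ln_tbil: float,
    slope_ln_tbil: float,
    auc_ln_plt: float,
) -> float:
    """7-day graft-assessment score.  ``auc_inr`` is raw-scale and must be
    positive: the formula takes its log."""
    if auc_inr <= 0:
        raise ValueError(f"AUC INR must be positive (its log is taken), got {auc_inr}")
    return (
        6.9647
        - 0.5799 * auc_ln_ast
        + 0.00844 * auc_ln_ast**2
        + 5.25347 * slope_ln_ast
        + 4.65046 * slope_ln_ast**2
        + 1.14098 * math.log(auc_inr)
        - 0.03475 * auc_ln_tbil
        + 0.00562 * auc_ln_tbil**2
        + 4.31135 * slope_ln_tbil
        + 5.84724 * slope_ln_tbil**2
        - 0.05115 * auc_ln_plt
    )


def lgraft10_linear_predictor(
    auc_ln_ast: float,
    slope7_ln_ast: float,
    max_inr: float,
    auc_ln_tbil: float,
    slope_ln_tbil: float,
    auc_ln_plt: float,
    slope_ln_plt: float,
) -> float:
    """10-day graft-assessment score; the AST slope is the 7-day one and the
    INR enters as log of the 10-day maximum (must be positive)."""
    if max_inr <= 0:
        raise ValueError(f"max INR must be positive (its log is taken), got {max_inr}")
    return (
        9.77
        - 0.42926 * auc_ln_ast
        + 0.00462 * auc_ln_ast**2
        + 4.60719 * slope7_ln_ast
        + 4.4129 * slope7_ln_ast**2
        + 0.88974 * math.log(max_inr)
        - 0.04852 * auc_ln_tbil
        + 0.00363 * auc_ln_tbil**2
        + 5.33627 * slope_ln_tbil
        - 0.04621 * auc_ln_plt
        - 5.24897 * slope_ln_plt
        + 13.08633 * slope_ln_plt**2
    )


def ease_linear_predictor(
    meld: float,
    rbc_units: float,
    thrombosis: bool,
    auc_ln_ast: float,
    auc_ln_plt: float,
    slope_ln_plt: float,
    slope_ln_tbil: float,
    center_volume_ge70: bool,
) -> float:
    """Simplified-estimation score; note the AST term is the SQUARE of the
    AUC of ln AST over PODs 1,2,3,7,10."""
    return (
        -0.602
        + 0.044 * meld
        + 0.065 * rbc_units
        + (2.567 if thrombosis else 0.0)
        + 0.000534 * auc_ln_ast**2
        - 0.093 * auc_ln_plt
        - 7.766 * slope_ln_plt
        + 0.795 * slope_ln_tbil
        + (-0.402 if center_volume_ge70 else 0.0)
    )


def ease_score(clin: ClinicalRecord, f: ft.EaseFeatures) -> tuple[float, int]:
    """Evaluate the simplified-estimation score for a patient; returns
    (score, risk group)."""
    missing = [
        name
        for name, value in (("meld", clin.meld), ("rbc_units", clin.rbc_units))
        if value is None
    ]
    if missing:
        raise InsufficientLabs(
            f"patient {clin.patient_id}: missing clinical inputs {missing}"
        )
    score = ease_linear_predictor(
        meld=clin.meld,
        rbc_units=clin.rbc_units,
        thrombosis=clin.thrombosis_days_1_10,
        auc_ln_ast=f.auc_ln_ast,
        auc_ln_plt=f.auc_ln_plt,
        slope_ln_plt=f.slope_ln_plt,
        slope_ln_tbil=f.slope_ln_tbil,
        center_volume_ge70=clin.center_volume_ge70,
    )
    return score, assign_risk_group(score, "ease").group


# ---------------------------------------------------------------------------
# risk-group bins


@dataclass(frozen=True)
class RiskGroup:
    group: int
    high: bool | None = None  # defined for the 7-day score only (groups 4-7)


def _warn_clamp(model: str, score: float, group: int) -> int:
    warnings.warn(
        f"{model} score {score} outside the published bins; clamped to "
        f"terminal group {group}",
        stacklevel=3,
    )
    return group


def assign_risk_group(score: float, model: str) -> RiskGroup:
    """Map a finite score to its published risk group.

    Published bin conventions: 3-day score bins are right-closed; both graft
    -assessment score bin lists are left-closed; the simplified-estimation
    score is rounded to 2 decimals first (its printed bounds are 2-dp).
    Out-of-range scores clamp to the terminal bins with a warning.
    """
    if not math.isfinite(score):
        raise ValueError(f"score must be finite, got {score}")
    if model == "meaf":
        if score <= 0:
            group = _warn_clamp(model, score, 1)
        elif score <= 2:
            group = 1
        elif score <= 5:
            group = 2
        elif score <= 6:
            group = 3
        elif score <= 8:
            group = 4
        elif score <= 10:
            group = 5
        else:
            group = _warn_clamp(model, score, 5)
        return RiskGroup(group)
    if model == "lgraft7":
        if score < -3.5:
            group = 1
        elif score < -2.5:
            group = 2
        elif score < -1.5:
            group = 3
        elif score < -0.5:
            group = 4
        elif score < 0.5:
            group = 5
        elif score < 1.5:
            group = 6
        elif score < 7.5:
            group = 7
        else:
            group = _warn_clamp(model, score, 7)
        return RiskGroup(group, high=group >= 4)
    if model == "lgraft10":
        if score < -3.23:
            group = 1
        elif score < -1.18:
            group = 2
        elif score < -0.57:
            group = 3
        elif score < 1.3:
            group = 4
        else:
            group = 5
        return RiskGroup(group)
    if model == "ease":
        r = round(score, 2)
        if r < -3.43:
            group = 1
        elif r <= -1.26:
            group = 2
        elif r <= -0.75:
            group = 3
        elif r <= -0.01:
            group = 4
        elif r <= 5:
            group = 5
        else:
            group = _warn_clamp(model, score, 5)
        return RiskGroup(group)
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# per-patient panel


@dataclass
class ScorePanel:
    """Every score whose sufficiency rule passes; the rest are None."""

    patient_id: str
    ead: EadResult | None
    meaf: MeafResult | None
    lgraft7: float | None
    lgraft7_group: int | None
    lgraft7_high: bool | None
    lgraft10: float | None
    lgraft10_group: int | None
    ease: float | None
    ease_group: int | None
    sufficiency: dict[str, bool]


def score_panel(
    labs: LabSeries, clin: ClinicalRecord, normalized: bool = False
) -> ScorePanel:
    """Compute all five scores for one patient, flagging insufficient ones."""
    sufficiency = {m: False for m in ft.MODELS}
    ead = meaf = None
    lg7 = lg7_group = lg7_high = lg10 = lg10_group = ease_val = ease_group = None

    try:
        ead = classify_ead(labs)
        sufficiency["ead"] = True
    except InsufficientLabs:
        pass
    try:
        meaf = meaf_score(ft.meaf_inputs(labs))
        sufficiency["meaf"] = True
    except InsufficientLabs:
        pass
    try:
        f7 = ft.lgraft7_features(labs, normalized=normalized)
        lg7 = lgraft7_linear_predictor(
            f7.auc_ln_ast, f7.slope_ln_ast, f7.auc_inr,
            f7.auc_ln_tbil, f7.slope_ln_tbil, f7.auc_ln_plt,
        )
        rg = assign_risk_group(lg7, "lgraft7")
        lg7_group, lg7_high = rg.group, rg.high
        sufficiency["lgraft7"] = True
    except InsufficientLabs:
        pass
    try:
        f10 = ft.lgraft10_features(labs, normalized=normalized)
        lg10 = lgraft10_linear_predictor(
            f10.auc_ln_ast, f10.slope7_ln_ast, f10.max_inr,
            f10.auc_ln_tbil, f10.slope_ln_tbil, f10.auc_ln_plt, f10.slope_ln_plt,
        )
        lg10_group = assign_risk_group(lg10, "lgraft10").group
        sufficiency["lgraft10"] = True
    except InsufficientLabs:
        pass
    try:
        fe = ft.ease_features(labs, normalized=normalized)
        ease_val, ease_group = ease_score(clin, fe)
        sufficiency["ease"] = True
    except InsufficientLabs:
        pass

    return ScorePanel(
        patient_id=labs.patient_id,
        ead=ead,
        meaf=meaf,
        lgraft7=lg7,
        lgraft7_group=lg7_group,
        lgraft7_high=lg7_high,
        lgraft10=lg10,
        lgraft10_group=lg10_group,
        ease=ease_val,
        ease_group=ease_group,
        sufficiency=sufficiency,
    )


def panel_row(panel: ScorePanel) -> dict:
    """Flatten a panel into the ``scores.csv`` column layout."""
    row: dict = {"patient_id": panel.patient_id}
    if panel.ead is not None:
        row.update(
            ead=int(panel.ead.positive),
            ead_criterion_1=int(panel.ead.bilirubin_ge_10),
            ead_criterion_2=int(panel.ead.inr_ge_1_6),
            ead_criterion_3=int(panel.ead.transaminase_gt_2000),
        )
    if panel.meaf is not None:
        row.update(meaf=panel.meaf.score, meaf_group=panel.meaf.risk_group)
    if panel.lgraft7 is not None:
        row.update(
            lgraft7=panel.lgraft7,
            lgraft7_group=panel.lgraft7_group,
            lgraft7_high=int(panel.lgraft7_high),
        )
    if panel.lgraft10 is not None:
        row.update(lgraft10=panel.lgraft10, lgraft10_group=panel.lgraft10_group)
    if panel.ease is not None:
        row.update(ease=panel.ease, ease_group=panel.ease_group)
    for model, ok in panel.sufficiency.items():
        row[f"sufficient_{model}"] = int(ok)
    return row
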