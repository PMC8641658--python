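"""Trajectory features: AUC and slope of (log-)lab curves over POD windows.

These are the regressors of the L-GrAFT and EASE scores.  Conventions, made
explicit because the published formulas do not state them:

* AUC is the **unnormalized** trapezoid of the (transformed) value against
  POD over the model's window.  A ``normalized`` switch divides by the window
  span for the time-averaged alternative.
* Missing interior PODs are bridged implicitly by the trapezoid (linear
  interpolation between observed neighbours).  When the first/last window
  days are unobserved, the observed-span area is rescaled by
  ``full span / observed span`` so magnitudes stay comparable across patients
  with POD 8–10 gaps.
* Slope is the ordinary-least-squares slope of the transformed value on POD
  over the same window (and POD subset) as the AUC.
* Where a formula names an explicit POD subset (the simplified-estimation
  score uses AST on PODs 1,2,3,7,10 and PLT/bilirubin on PODs 1,3,7,10),
  observations outside the subset are ignored entirely.

Coverage rule for "insufficient laboratory values": an AUC/slope model needs,
for every required (analyte, window), at least 3 observations with at least
one in the first 2 window days and one in the last 3.  The 3-day-max model
additionally requires the POD-3 bilirubin exactly (no fallback).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .cohort import Cohort, LabSeries
from .errors import InsufficientLabs

MODELS = ("ead", "meaf", "lgraft7", "lgraft10", "ease")

LGRAFT7_WINDOW = (1, 7)
LGRAFT10_WINDOW = (1, 10)
EASE_AST_PODS = (1, 2, 3, 7, 10)
EASE_PLT_TBIL_PODS = (1, 3, 7, 10)
MEAF_WINDOW = (1, 3)


def _restrict(
    pods: np.ndarray,
    values: np.ndarray,
    window: tuple[int, int],
    pod_subset: tuple[int, ...] | None,
) -> tuple[np.ndarray, np.ndarray]:
    mask = (pods >= window[0]) & (pods <= window[1])
    if pod_subset is not None:
        mask &= np.isin(pods, pod_subset)
    return pods[mask], values[mask]


def trapezoid_auc(
    pods,
    values,
    window: tuple[int, int],
    transform: str = "ln",
    pod_subset: tuple[int, ...] | None = None,
    normalized: bool = False,
) -> float:
    """Trapezoidal area of transform(value) vs POD over ``window``.

    Raises :class:`InsufficientLabs` when fewer than 2 observations remain
    after restriction.  ``transform`` is ``"ln"`` or ``"identity"``.
    """
    pods = np.asarray(pods, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(pods)
    pods, values = pods[order], values[order]
    pods, values = _restrict(pods, values, window, pod_subset)
    if pods.size < 2:
        raise InsufficientLabs(
            f"need >=2 observations in window {window}, have {pods.size}"
        )
    if transform == "ln":
        if np.any(values <= 0):
            raise ValueError("non-positive value under ln transform")
        tv = np.log(values)
    elif transform == "identity":
        tv = values
    else:
        raise ValueError(f"unknown transform {transform!r}")
    area = float(np.trapezoid(tv, pods))
    observed_span = pods[-1] - pods[0]
    full_span = window[1] - window[0]
    if observed_span < full_span:
        area *= full_span / observed_span
    if normalized:
        area /= full_span
    return area


def ols_slope(
    pods,
    values,
    window: tuple[int, int],
    transform: str = "ln",
    pod_subset: tuple[int, ...] | None = None,
) -> float:
    """OLS slope (per day) of transform(value) on POD over ``window``."""
    pods = np.asarray(pods, dtype=float)
    values = np.asarray(values, dtype=float)
    pods, values = _restrict(pods, values, window, pod_subset)
    if np.unique(pods).size < 2:
        raise InsufficientLabs(
            f"need >=2 distinct PODs in window {window}, have {np.unique(pods).size}"
        )
    if transform == "ln":
        if np.any(values <= 0):
            raise ValueError("non-positive value under ln transform")
        tv = np.log(values)
    elif transform == "identity":
        tv = values
    else:
        raise ValueError(f"unknown transform {transform!r}")
    p_centered = pods - pods.mean()
    return float(p_centered @ (tv - tv.mean()) / (p_centered @ p_centered))


# ---------------------------------------------------------------------------
# coverage ("insufficient laboratory values") rules

_AUC_COVERAGE: dict[str, list[tuple[str, tuple[int, int], tuple[int, ...] | None]]] = {
    "lgraft7": [
        ("AST", LGRAFT7_WINDOW, None),
        ("INR", LGRAFT7_WINDOW, None),
        ("TBIL", LGRAFT7_WINDOW, None),
        ("PLT", LGRAFT7_WINDOW, None),
    ],
    "lgraft10": [
        ("AST", LGRAFT10_WINDOW, None),
        ("AST", LGRAFT7_WINDOW, None),  # the 7-day AST slope term
        ("INR", LGRAFT10_WINDOW, None),
        ("TBIL", LGRAFT10_WINDOW, None),
        ("PLT", LGRAFT10_WINDOW, None),
    ],
    "ease": [
        ("AST", LGRAFT10_WINDOW, EASE_AST_PODS),
        ("PLT", LGRAFT10_WINDOW, EASE_PLT_TBIL_PODS),
        ("TBIL", LGRAFT10_WINDOW, EASE_PLT_TBIL_PODS),
    ],
}


def _window_covered(
    labs: LabSeries,
    analyte: str,
    window: tuple[int, int],
    pod_subset: tuple[int, ...] | None,
) -> tuple[bool, str | None]:
    pods, _ = labs.series(analyte, window=window, pod_subset=pod_subset)
    if pods.size < 3:
        return False, f"{analyte}: {pods.size} observations in window {window} (<3)"
    if not np.any(pods <= window[0] + 1):
        return False, f"{analyte}: no observation in first 2 days of window {window}"
    if not np.any(pods >= window[1] - 2):
        return False, f"{analyte}: no observation in last 3 days of window {window}"
    return True, None


def coverage(labs: LabSeries, model: str) -> tuple[bool, str | None]:
    """Whether ``labs`` suffice to compute ``model``; reason when not."""
    if model in _AUC_COVERAGE:
        for analyte, window, subset in _AUC_COVERAGE[model]:
            ok, reason = _window_covered(labs, analyte, window, subset)
            if not ok:
                return False, reason
        return True, None
    if model == "meaf":
        for analyte in ("ALT", "INR"):
            if not labs.series(analyte, window=MEAF_WINDOW)[0].size:
                return False, f"{analyte}: no observation on PODs 1-3"
        if labs.value_at("TBIL", 3) is None:
            return False, "TBIL: POD-3 value required"
        return True, None
    if model == "ead":
        if labs.value_at("TBIL", 7) is None:
            return False, "TBIL: POD-7 value required"
        if labs.value_at("INR", 7) is None:
            return False, "INR: POD-7 value required"
        for analyte in ("ALT", "AST"):
            if not labs.series(analyte, window=(1, 7))[0].size:
                return False, f"{analyte}: no observation on PODs 1-7"
        return True, None
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# per-model feature bundles


@dataclass(frozen=True)
class Lgraft7Features:
    """Regressors of the 7-day graft-assessment score (window PODs 1-7).

    ``auc_inr`` is on the raw INR scale — the score logs it.
    """

    auc_ln_ast: float
    slope_ln_ast: float
    auc_inr: float
    auc_ln_tbil: float
    slope_ln_tbil: float
    auc_ln_plt: float


@dataclass(frozen=True)
class Lgraft10Features:
    """Regressors of the 10-day score; AST slope stays on PODs 1-7 and the
    INR term is the log of the 10-day maximum."""

    auc_ln_ast: float
    slope7_ln_ast: float
    max_inr: float
    auc_ln_tbil: float
    slope_ln_tbil: float
    auc_ln_plt: float
    slope_ln_plt: float


@dataclass(frozen=True)
class EaseFeatures:
    """Trajectory regressors of the simplified-estimation score, built on the
    printed POD subsets (AST: 1,2,3,7,10; PLT/TBIL: 1,3,7,10)."""

    auc_ln_ast: float
    auc_ln_plt: float
    slope_ln_plt: float
    slope_ln_tbil: float


@dataclass(frozen=True)
class MeafInputs:
    """3-day maxima of ALT/INR and the POD-3 bilirubin (mg/dL)."""

    alt_max_3pod: float
    inr_max_3pod: float
    bilirubin_pod3: float


@dataclass(frozen=True)
class EadInputs:
    tbil_pod7: float
    inr_pod7: float
    alt_max_7: float
    ast_max_7: float


def _require(labs: LabSeries, model: str) -> None:
    ok, reason = coverage(labs, model)
    if not ok:
        raise InsufficientLabs(f"patient {labs.patient_id}, model {model}: {reason}")


def lgraft7_features(labs: LabSeries, normalized: bool = False) -> Lgraft7Features:
    _require(labs, "lgraft7")
    w = LGRAFT7_WINDOW
    return Lgraft7Features(
        auc_ln_ast=trapezoid_auc(*labs.series("AST"), w, "ln", normalized=normalized),
        slope_ln_ast=ols_slope(*labs.series("AST"), w, "ln"),
        auc_inr=trapezoid_auc(*labs.series("INR"), w, "identity", normalized=normalized),
        auc_ln_tbil=trapezoid_auc(*labs.series("TBIL"), w, "ln", normalized=normalized),
        slope_ln_tbil=ols_slope(*labs.series("TBIL"), w, "ln"),
        auc_ln_plt=trapezoid_auc(*labs.series("PLT"), w, "ln", normalized=normalized),
    )


def lgraft10_features(labs: LabSeries, normalized: bool = False) -> Lgraft10Features:
    _require(labs, "lgraft10")
    w = LGRAFT10_WINDOW
    return Lgraft10Features(
        auc_ln_ast=trapezoid_auc(*labs.series("AST"), w, "ln", normalized=normalized),
        slope7_ln_ast=ols_slope(*labs.series("AST"), LGRAFT7_WINDOW, "ln"),
        max_inr=labs.max_in("INR", *w),
        auc_ln_tbil=trapezoid_auc(*labs.series("TBIL"), w, "ln", normalized=normalized),
        slope_ln_tbil=ols_slope(*labs.series("TBIL"), w, "ln"),
        auc_ln_plt=trapezoid_auc(*labs.series("PLT"), w, "ln", normalized=normalized),
        slope_ln_plt=ols_slope(*labs.series("PLT"), w, "ln"),
    )


def ease_features(labs: LabSeries, normalized: bool = False) -> EaseFeatures:
    _require(labs, "ease")
    w = LGRAFT10_WINDOW
    return EaseFeatures(
        auc_ln_ast=trapezoid_auc(
            *labs.series("AST"), w, "ln", pod_subset=EASE_AST_PODS, normalized=normalized
        ),
        auc_ln_plt=trapezoid_auc(
            *labs.series("PLT"), w, "ln", pod_subset=EASE_PLT_TBIL_PODS, normalized=normalized
        ),
        slope_ln_plt=ols_slope(
            *labs.series("PLT"), w, "ln", pod_subset=EASE_PLT_TBIL_PODS
        ),
        slope_ln_tbil=ols_slope(
            *labs.series("TBIL"), w, "ln", pod_subset=EASE_PLT_TBIL_PODS
        ),
    )


def meaf_inputs(labs: LabSeries) -> MeafInputs:
    _require(labs, "meaf")
    return MeafInputs(
        alt_max_3pod=labs.max_in("ALT", *MEAF_WINDOW),
        inr_max_3pod=labs.max_in("INR", *MEAF_WINDOW),
        bilirubin_pod3=labs.value_at("TBIL", 3),
    )


def ead_inputs(labs: LabSeries) -> EadInputs:
    _require(labs, "ead")
    return EadInputs(
        tbil_pod7=labs.value_at("TBIL", 7),
        inr_pod7=labs.value_at("INR", 7),
        alt_max_7=labs.max_in("ALT", 1, 7),
        ast_max_7=labs.max_in("AST", 1, 7),
    )


_EXTRACTORS = {
    "lgraft7": lgraft7_features,
    "lgraft10": lgraft10_features,
    "ease": ease_features,
}


def extract_features(labs: LabSeries, model: str, normalized: bool = False):
    """Dispatch to the per-model feature builder.

    Raises :class:`InsufficientLabs` when the coverage rule fails.
    """
    if model in _EXTRACTORS:
        return _EXTRACTORS[model](labs, normalized=normalized)
    if model == "meaf":
        return meaf_inputs(labs)
    if model == "ead":
        return ead_inputs(labs)
    raise ValueError(f"unknown model {model!r}")


def features_table(cohort: Cohort, normalized: bool = False) -> pd.DataFrame:
    """Audit dump: one row per patient, all model features (NaN when a
    model's coverage rule fails)."""
    rows = []
    for pid in cohort.patient_ids():
        labs = cohort.labs[pid]
        row: dict = {"patient_id": pid}
        for model in MODELS:
            try:
                bundle = extract_features(labs, model, normalized=normalized) \
                    if model in _EXTRACTORS else extract_features(labs, model)
            except InsufficientLabs:
                continue
            for name, value in asdict(bundle).items():
                row[f"{model}_{name}"] = value
        rows.append(row)
    return pd.DataFrame(rows)
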