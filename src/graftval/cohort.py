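"""Domain types, canonical units, CSV readers/writers and the eligibility filter.

A cohort is three aligned per-patient collections:

* :class:`LabSeries` — post-operative-day (POD) indexed values of the five
  analytes (AST, ALT, TBIL, INR, PLT) in canonical units,
* :class:`ClinicalRecord` — recipient / donor / operation covariates plus the
  study exclusion flags,
* :class:`OutcomeRecord` — death / retransplant / censoring follow-up.

Canonical units: AST/ALT in IU/L, total bilirubin in mg/dL (values supplied in
µmol/L are divided by 17.104 on ingest), INR dimensionless, platelets in
10^9/L.  Missing values are absent rows, never sentinels.  POD 0 rows are
accepted on input but all score windows start at POD 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .errors import CohortFormatError, LabValueError

ANALYTES = ("AST", "ALT", "TBIL", "INR", "PLT")

#: canonical unit written on output, per analyte
CANONICAL_UNITS = {
    "AST": "IU/L",
    "ALT": "IU/L",
    "TBIL": "mg/dL",
    "INR": "",
    "PLT": "1e9/L",
}

#: µmol/L of bilirubin per mg/dL
UMOL_PER_MGDL = 17.104

_TBIL_UMOL_ALIASES = {"umol/l", "µmol/l", "μmol/l", "umol"}


def _convert_to_canonical(analyte: str, value: float, unit: str) -> float:
    """Convert ``value`` with declared ``unit`` to the analyte's canonical unit."""
    u = (unit or "").strip().lower()
    if analyte == "TBIL" and u in _TBIL_UMOL_ALIASES:
        return value / UMOL_PER_MGDL
    canonical = CANONICAL_UNITS[analyte].lower()
    if u in ("", canonical, canonical.replace("1e9/l", "10^9/l")):
        return value
    if analyte == "PLT" and u in ("1e9/l", "10^9/l", "x10^9/l", "g/l"):
        return value
    if analyte in ("AST", "ALT") and u in ("iu/l", "u/l"):
        return value
    if analyte == "TBIL" and u in ("mg/dl",):
        return value
    raise LabValueError(f"unknown unit {unit!r} for analyte {analyte}")


@dataclass
class LabSeries:
    """POD-indexed laboratory observations for one patient.

    ``observations`` maps ``(analyte, pod)`` to a strictly positive value in
    canonical units; duplicates per key are forbidden.
    """

    patient_id: str
    observations: dict[tuple[str, int], float] = field(default_factory=dict)

    def add(self, analyte: str, pod: int, value: float, unit: str = "") -> None:
        if analyte not in ANALYTES:
            raise LabValueError(
                f"patient {self.patient_id}: unknown analyte {analyte!r}"
            )
        pod = int(pod)
        if pod < 0:
            raise LabValueError(f"patient {self.patient_id}: negative POD {pod}")
        value = _convert_to_canonical(analyte, float(value), unit)
        if not math.isfinite(value) or value <= 0:
            raise LabValueError(
                f"patient {self.patient_id}: non-positive {analyte} value "
                f"{value!r} on POD {pod} (log-transform undefined)"
            )
        key = (analyte, pod)
        if key in self.observations:
            raise LabValueError(
                f"patient {self.patient_id}: duplicate {analyte} observation on POD {pod}"
            )
        self.observations[key] = value

    def pods(self, analyte: str) -> list[int]:
        """Sorted PODs with an observation of ``analyte``."""
        return sorted(p for (a, p) in self.observations if a == analyte)

    def series(
        self,
        analyte: str,
        window: tuple[int, int] | None = None,
        pod_subset: tuple[int, ...] | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (pods, values) sorted by POD, optionally restricted.

        ``window`` keeps PODs in [start, end]; ``pod_subset`` additionally
        keeps only the named PODs.
        """
        pairs = []
        for (a, p), v in self.observations.items():
            if a != analyte:
                continue
            if window is not None and not (window[0] <= p <= window[1]):
                continue
            if pod_subset is not None and p not in pod_subset:
                continue
            pairs.append((p, v))
        pairs.sort()
        if not pairs:
            return np.empty(0, dtype=int), np.empty(0)
        pods, values = zip(*pairs)
        return np.asarray(pods, dtype=int), np.asarray(values, dtype=float)

    def value_at(self, analyte: str, pod: int) -> float | None:
        return self.observations.get((analyte, int(pod)))

    def max_in(self, analyte: str, start: int, end: int) -> float | None:
        _, values = self.series(analyte, window=(start, end))
        return float(values.max()) if values.size else None


# ordered per the study's printed exclusion list; a patient is tallied once,
# in the first matching category
EXCLUSION_CATEGORIES = (
    ("age_lt_18", "excl_age_lt18"),
    ("acute_liver_failure", "excl_acute_liver_failure"),
    ("retransplantation", "excl_retransplant"),
    ("multivisceral", "excl_multivisceral"),
    ("split_liver", "excl_split"),
    ("living_donor", "excl_living_donor"),
    ("early_vascular_complication", "excl_early_vascular"),
    ("insufficient_labs", None),  # computed from lab coverage
)


@dataclass
class ClinicalRecord:
    """One-row-per-patient covariates and exclusion flags."""

    patient_id: str
    # recipient
    recipient_age: float | None = None
    recipient_male: bool | None = None
    recipient_bmi: float | None = None
    diagnosis: str | None = None
    meld: float | None = None
    preop_crea_umol_l: float | None = None
    preop_tbil_umol_l: float | None = None
    preop_inr: float | None = None
    child_pugh: float | None = None
    diabetes: bool | None = None
    hypertension: bool | None = None
    cardiovascular_disease: bool | None = None
    # donor
    donor_age: float | None = None
    donor_male: bool | None = None
    donor_bmi: float | None = None
    cause_of_death: str | None = None
    donation_category: str | None = None  # DBD / DCD / DBCD
    dri: float | None = None
    # operation
    anhepatic_min: float | None = None
    cit_min: float | None = None
    operation_min: float | None = None
    rbc_units: float | None = None
    ffp_units: float | None = None
    hemorrhage_ml: float | None = None
    # EASE indicators
    thrombosis_days_1_10: bool = False
    center_volume_ge70: bool = False
    # exclusion flags
    excl_age_lt18: bool = False
    excl_acute_liver_failure: bool = False
    excl_retransplant: bool = False
    excl_multivisceral: bool = False
    excl_split: bool = False
    excl_living_donor: bool = False
    excl_early_vascular: bool = False

    def __post_init__(self) -> None:
        if self.meld is not None and self.meld < 6:
            raise ValueError(f"patient {self.patient_id}: MELD {self.meld} < 6")
        if self.cit_min is not None and self.cit_min <= 0:
            raise ValueError(f"patient {self.patient_id}: CIT must be > 0")
        if self.rbc_units is not None and self.rbc_units < 0:
            raise ValueError(f"patient {self.patient_id}: RBC units < 0")
        if self.donation_category is not None and self.donation_category not in (
            "DBD",
            "DCD",
            "DBCD",
        ):
            raise ValueError(
                f"patient {self.patient_id}: unknown donation category "
                f"{self.donation_category!r}"
            )


@dataclass
class OutcomeRecord:
    """Death / retransplant / censoring follow-up for one patient."""

    patient_id: str
    follow_up_days: float
    death: bool = False
    death_day: float | None = None
    retransplant: bool = False
    retransplant_day: float | None = None

    def __post_init__(self) -> None:
        for flag, day, name in (
            (self.death, self.death_day, "death"),
            (self.retransplant, self.retransplant_day, "retransplant"),
        ):
            if flag and day is None:
                raise ValueError(f"patient {self.patient_id}: {name} flag without day")
            if day is not None and day > self.follow_up_days:
                raise ValueError(
                    f"patient {self.patient_id}: {name} day {day} exceeds "
                    f"follow-up {self.follow_up_days}"
                )

    @property
    def graft_loss_day(self) -> float | None:
        """Earliest of death / retransplant day, or None if neither occurred."""
        days = [
            d
            for flag, d in ((self.death, self.death_day), (self.retransplant, self.retransplant_day))
            if flag
        ]
        return min(days) if days else None

    @property
    def graft_loss(self) -> bool:
        return self.death or self.retransplant


@dataclass
class Cohort:
    """Aligned per-patient collections keyed by patient_id."""

    labs: dict[str, LabSeries]
    clinical: dict[str, ClinicalRecord]
    outcomes: dict[str, OutcomeRecord]

    def __post_init__(self) -> None:
        keys = set(self.labs)
        if set(self.clinical) != keys or set(self.outcomes) != keys:
            raise ValueError("cohort collections are not aligned on patient_id")

    def patient_ids(self) -> list[str]:
        return sorted(self.labs)

    def __len__(self) -> int:
        return len(self.labs)

    def subset(self, ids) -> "Cohort":
        ids = list(ids)
        return Cohort(
            labs={i: self.labs[i] for i in ids},
            clinical={i: self.clinical[i] for i in ids},
            outcomes={i: self.outcomes[i] for i in ids},
        )


_BOOL_CLINICAL_FIELDS = {
    "recipient_male",
    "donor_male",
    "diabetes",
    "hypertension",
    "cardiovascular_disease",
    "thrombosis_days_1_10",
    "center_volume_ge70",
    "excl_age_lt18",
    "excl_acute_liver_failure",
    "excl_retransplant",
    "excl_multivisceral",
    "excl_split",
    "excl_living_donor",
    "excl_early_vascular",
}
_STR_CLINICAL_FIELDS = {"patient_id", "diagnosis", "cause_of_death", "donation_category"}
_OUTCOME_COLUMNS = ("follow_up_days", "death", "death_day", "retransplant", "retransplant_day")


def _clinical_from_row(row: pd.Series) -> ClinicalRecord:
    kwargs = {}
    for f in fields(ClinicalRecord):
        if f.name not in row or pd.isna(row[f.name]):
            continue
        v = row[f.name]
        if f.name in _BOOL_CLINICAL_FIELDS:
            kwargs[f.name] = bool(int(v))
        elif f.name in _STR_CLINICAL_FIELDS:
            kwargs[f.name] = str(v)
        else:
            kwargs[f.name] = float(v)
    return ClinicalRecord(**kwargs)


def _outcome_from_row(row: pd.Series) -> OutcomeRecord:
    def _num(col):
        return None if col not in row or pd.isna(row[col]) else float(row[col])

    return OutcomeRecord(
        patient_id=str(row["patient_id"]),
        follow_up_days=float(row["follow_up_days"]),
        death=bool(int(row.get("death", 0) or 0)),
        death_day=_num("death_day"),
        retransplant=bool(int(row.get("retransplant", 0) or 0)),
        retransplant_day=_num("retransplant_day"),
    )


def read_cohort(lab_path, clinical_path) -> Cohort:
    """Read the labs CSV and the clinical/outcome CSV into a :class:`Cohort`.

    Labs file columns: ``patient_id, pod, analyte, value, unit`` (one
    observation per row).  Clinical file: one row per patient with the
    :class:`ClinicalRecord` column dictionary plus the outcome columns;
    booleans are encoded 0/1.  Unparseable rows are reported with their
    1-based file line numbers.
    """
    labs_df = pd.read_csv(
        lab_path,
        dtype={"patient_id": str, "analyte": str, "unit": str},
        float_precision="round_trip",
    )
    clin_df = pd.read_csv(clinical_path, dtype={"patient_id": str}, float_precision="round_trip")

    labs: dict[str, LabSeries] = {}
    bad_rows: list[str] = []
    for idx, row in enumerate(labs_df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        try:
            pid = str(row.patient_id)
            series = labs.setdefault(pid, LabSeries(patient_id=pid))
            unit = "" if pd.isna(getattr(row, "unit", "")) else str(row.unit)
            series.add(str(row.analyte), int(row.pod), float(row.value), unit)
        except (LabValueError, ValueError, TypeError) as exc:
            bad_rows.append(f"{lab_path} line {line}: {exc}")
    if bad_rows:
        raise CohortFormatError("unparseable laboratory rows", bad_rows)

    clinical: dict[str, ClinicalRecord] = {}
    outcomes: dict[str, OutcomeRecord] = {}
    for idx, (_, row) in enumerate(clin_df.iterrows()):
        line = idx + 2
        try:
            rec = _clinical_from_row(row)
            clinical[rec.patient_id] = rec
            outcomes[rec.patient_id] = _outcome_from_row(row)
        except (ValueError, KeyError, TypeError) as exc:
            bad_rows.append(f"{clinical_path} line {line}: {exc}")
    if bad_rows:
        raise CohortFormatError("unparseable clinical rows", bad_rows)

    for pid in clinical:
        labs.setdefault(pid, LabSeries(patient_id=pid))
    missing = set(labs) - set(clinical)
    if missing:
        raise CohortFormatError(
            f"lab rows for patients absent from the clinical file: {sorted(missing)}"
        )
    return Cohort(labs=labs, clinical=clinical, outcomes=outcomes)


def write_cohort(cohort: Cohort, lab_path, clinical_path) -> None:
    """Write the two cohort CSVs in canonical units (inverse of read_cohort)."""
    lab_rows = []
    for pid in cohort.patient_ids():
        series = cohort.labs[pid]
        for (analyte, pod), value in sorted(series.observations.items()):
            lab_rows.append(
                {
                    "patient_id": pid,
                    "pod": pod,
                    "analyte": analyte,
                    "value": repr(value),
                    "unit": CANONICAL_UNITS[analyte],
                }
            )
    pd.DataFrame(
        lab_rows, columns=["patient_id", "pod", "analyte", "value", "unit"]
    ).to_csv(lab_path, index=False)

    clin_rows = []
    for pid in cohort.patient_ids():
        rec = cohort.clinical[pid]
        out = cohort.outcomes[pid]
        row: dict = {}
        for f in fields(ClinicalRecord):
            v = getattr(rec, f.name)
            if v is None:
                row[f.name] = ""
            elif f.name in _BOOL_CLINICAL_FIELDS:
                row[f.name] = int(v)
            else:
                row[f.name] = v
        row["follow_up_days"] = out.follow_up_days
        row["death"] = int(out.death)
        row["death_day"] = "" if out.death_day is None else out.death_day
        row["retransplant"] = int(out.retransplant)
        row["retransplant_day"] = "" if out.retransplant_day is None else out.retransplant_day
        clin_rows.append(row)
    cols = [f.name for f in fields(ClinicalRecord)] + list(_OUTCOME_COLUMNS)
    pd.DataFrame(clin_rows, columns=cols).to_csv(clinical_path, index=False)


def apply_exclusions(cohort: Cohort) -> tuple[Cohort, dict[str, int]]:
    """Filter the cohort by the study's eligibility criteria.

    Each excluded patient is tallied once, under the first matching category
    in the printed order; ``insufficient_labs`` is evaluated last, via the
    trajectory-feature coverage rule (a patient must be able to support every
    score model).  Returns the retained cohort and the per-category tally.
    """
    from .features import coverage, MODELS  # local import: avoid module cycle

    tally = {name: 0 for name, _ in EXCLUSION_CATEGORIES}
    keep: list[str] = []
    for pid in cohort.patient_ids():
        rec = cohort.clinical[pid]
        category = None
        for name, attr in EXCLUSION_CATEGORIES:
            if attr is not None and getattr(rec, attr):
                category = name
                break
        if category is None:
            for model in MODELS:
                ok, _ = coverage(cohort.labs[pid], model)
                if not ok:
                    category = "insufficient_labs"
                    break
        if category is None:
            keep.append(pid)
        else:
            tally[category] += 1
    return cohort.subset(keep), tally
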