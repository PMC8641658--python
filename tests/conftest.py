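import math

import pytest

from graftval.cohort import ClinicalRecord, Cohort, LabSeries, OutcomeRecord


def make_labs(pid: str, table: dict[str, dict[int, float]]) -> LabSeries:
    """Build a LabSeries from {analyte: {pod: value}}."""
    labs = LabSeries(patient_id=pid)
    for analyte, by_pod in table.items():
        for pod, value in by_pod.items():
            labs.add(analyte, pod, value)
    return labs


def complete_lab_table(peak_ast: float = 900.0) -> dict[str, dict[int, float]]:
    """Plausible full PODs 1-10 trajectories for all five analytes."""
    return {
        "AST": {p: peak_ast * math.exp(-0.3 * (p - 1)) for p in range(1, 11)},
        "ALT": {p: 700.0 * math.exp(-0.25 * (p - 1)) for p in range(1, 11)},
        "TBIL": {p: 3.0 * math.exp(-0.08 * (p - 1)) for p in range(1, 11)},
        "INR": {p: 1.4 * math.exp(-0.02 * (p - 1)) for p in range(1, 11)},
        "PLT": {p: 80.0 * math.exp(0.05 * (p - 1)) for p in range(1, 11)},
    }


@pytest.fixture
def complete_labs() -> LabSeries:
    return make_labs("PT1", complete_lab_table())


@pytest.fixture
def default_clinical() -> ClinicalRecord:
    return ClinicalRecord(
        patient_id="PT1",
        meld=15.0,
        cit_min=420.0,
        rbc_units=4.0,
        thrombosis_days_1_10=False,
        center_volume_ge70=True,
    )


def single_patient_cohort(
    labs: LabSeries,
    clinical: ClinicalRecord | None = None,
    outcome: OutcomeRecord | None = None,
) -> Cohort:
    pid = labs.patient_id
    clinical = clinical or ClinicalRecord(patient_id=pid, meld=12.0, rbc_units=2.0)
    outcome = outcome or OutcomeRecord(patient_id=pid, follow_up_days=400.0)
    return Cohort(labs={pid: labs}, clinical={pid: clinical}, outcomes={pid: outcome})


@pytest.fixture
def two_patient_cohort() -> Cohort:
    labs = {
        "A": make_labs("A", complete_lab_table(900.0)),
        "B": make_labs("B", complete_lab_table(2500.0)),
    }
    clinical = {
        "A": ClinicalRecord(patient_id="A", meld=10.0, cit_min=400.0, rbc_units=3.0),
        "B": ClinicalRecord(
            patient_id="B",
            meld=25.0,
            cit_min=520.0,
            rbc_units=9.0,
            thrombosis_days_1_10=True,
        ),
    }
    outcomes = {
        "A": OutcomeRecord(patient_id="A", follow_up_days=600.0),
        "B": OutcomeRecord(
            patient_id="B", follow_up_days=45.0, death=True, death_day=45.0
        ),
    }
    return Cohort(labs=labs, clinical=clinical, outcomes=outcomes)
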