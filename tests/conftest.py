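import pytest

from polyrisk import reference
from polyrisk.medlog import MedicationRecord, Patient
from polyrisk.synthetic import SyntheticConfig, generate_cohort, generate_formulary


@pytest.fixture(scope="session")
def formulary():
    return reference.packaged_formulary()


@pytest.fixture(scope="session")
def ruleset():
    return reference.packaged_ruleset()


@pytest.fixture(scope="session")
def kb():
    return reference.packaged_kb()


@pytest.fixture(scope="session")
def reference_tables():
    return reference.load_reference_tables()


@pytest.fixture(scope="session")
def synth():
    """One deterministic full-size synthetic cohort shared across tests."""
    config = SyntheticConfig(seed=123)
    fixtures = generate_formulary(config)
    cohort, truth = generate_cohort(config, fixtures)
    return config, fixtures, cohort, truth


def make_patient(pid="P1", age=75, meds=(), cancer=(), supportive=(), covs=None, ga=()):
    """Hand-built patient: meds are (name, category) pairs."""
    regular = [MedicationRecord(pid, n, n, c) for n, c in meds]
    cancer_meds = [
        MedicationRecord(pid, n, n, "prescription", is_cancer_treatment=True)
        for n in cancer
    ] + [
        MedicationRecord(pid, n, n, "prescription", is_supportive_care=True)
        for n in supportive
    ]
    return Patient(
        patient_id=pid,
        age_years=age,
        covariates=covs or {},
        ga_impairments=set(ga),
        regular_meds=regular,
        cancer_meds=cancer_meds,
    )
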