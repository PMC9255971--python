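"""Medication-log ingestion, normalization, and polypharmacy quantification.

A medication log is the per-patient record of every regular medication
(prescription, over-the-counter, or complementary/alternative) a patient
reports taking. Cancer treatments and supportive-care drugs are carried on
the patient but excluded from the regular-medication count, from
potentially-inappropriate-medication screening, and from the regular-drug
side of interaction detection.

Polypharmacy is defined as >= 5 regular medications; excessive polypharmacy
as >= 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import pct

logger = logging.getLogger(__name__)

CATEGORIES = ("prescription", "otc", "complementary")
NONPRESCRIPTION_CATEGORIES = ("otc", "complementary")

POLYPHARMACY_THRESHOLD = 5
EXCESSIVE_THRESHOLD = 10

#: Conservative blacklist of dose/route/schedule tokens stripped during name
#: normalization. Unrecognized tokens pass through untouched.
_DOSE_TOKENS = frozenset(
    {
        "mg", "mcg", "g", "gm", "ml", "units", "unit", "iu", "meq",
        "tablet", "tablets", "tab", "tabs", "capsule", "capsules", "cap",
        "caps", "softgel", "patch", "cream", "ointment", "solution", "spray",
        "oral", "po", "topical", "subcutaneous", "sq", "inhaled",
        "daily", "bid", "tid", "qid", "qd", "qhs", "prn", "weekly",
        "er", "xr", "sr", "cr", "la", "xl", "odt", "dr", "hfa",
        "ec", "enteric", "coated",
    }
)


@dataclass(frozen=True)
class MedicationRecord:
    """One normalized drug exposure for one patient."""

    patient_id: str
    raw_name: str
    generic_name: str
    category: str  # prescription | otc | complementary
    is_cancer_treatment: bool = False
    is_supportive_care: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown medication category: {self.category!r}")

    @property
    def is_regular(self) -> bool:
        """True when the record counts toward the regular-medication total."""
        return not (self.is_cancer_treatment or self.is_supportive_care)


@dataclass
class Patient:
    """One cohort member: covariates, geriatric-assessment flags, and meds.

    ``covariates`` is a flat categorical map (gender, race, education, income,
    marital_status, cancer_type, stage, treatment_line, life_expectancy,
    kps_band); ``ga_impairments`` is the set of impaired geriatric-assessment
    domains out of {function, physical, comorbidity, cognition, social,
    psychological, nutrition}.
    """

    patient_id: str
    age_years: int
    covariates: dict = field(default_factory=dict)
    ga_impairments: set = field(default_factory=set)
    regular_meds: list = field(default_factory=list)
    cancer_meds: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age_years < 70:
            raise ValueError(
                f"patient {self.patient_id}: age {self.age_years} < 70"
            )

    def regular_records(self) -> list:
        """Regular (non-cancer, non-supportive) medication records."""
        return [m for m in self.regular_meds if m.is_regular]

    def cancer_treatment_records(self) -> list:
        """Cancer-treatment records; supportive-care drugs are excluded."""
        return [m for m in self.cancer_meds if m.is_cancer_treatment]


@dataclass(frozen=True)
class CohortSummary:
    n_patients: int
    n_med_occurrences: int
    n_distinct_generics: int
    median_meds: float
    range_meds: tuple
    pct_polypharmacy: float
    pct_excessive_polypharmacy: float
    pct_nonprescription_of_total: float

    def __post_init__(self) -> None:
        for p in (
            self.pct_polypharmacy,
            self.pct_excessive_polypharmacy,
            self.pct_nonprescription_of_total,
        ):
            if not 0.0 <= p <= 100.0:
                raise ValueError("percentage outside [0, 100]")
        if self.pct_excessive_polypharmacy > self.pct_polypharmacy:
            raise ValueError("excessive polypharmacy cannot exceed polypharmacy")
        if self.n_med_occurrences < self.n_distinct_generics:
            raise ValueError("occurrences cannot be fewer than distinct generics")


def normalize_name(raw: str) -> str:
    """Lowercase a recorded drug name and strip dose/route suffix tokens.

    Tokens that are pure numbers, numbers glued to a unit ("20mg"), or in the
    dose-token blacklist are dropped; everything else passes through, so an
    unrecognized brand or compound name survives intact.
    """
    tokens = raw.strip().lower().replace(",", " ").split()
    kept = []
    for tok in tokens:
        if tok in _DOSE_TOKENS:
            continue
        # pure number, or number glued to a unit ("20mg", "0.5ml")
        if tok.replace(".", "", 1).replace("/", "", 1).isdigit():
            continue
        head = tok.rstrip("abcdefghijklmnopqrstuvwxyz")
        tail = tok[len(head):]
        if head and head.replace(".", "", 1).isdigit() and tail in _DOSE_TOKENS:
            continue
        kept.append(tok)
    return " ".join(kept)


def normalize_and_dedupe(
    records: Iterable[MedicationRecord],
    synonyms: Mapping[str, str] | None = None,
) -> list:
    """Map brand names to generics and collapse within-patient duplicates.

    Names are normalized (lowercase, dose tokens stripped), mapped through the
    brand->generic synonym table (identity when absent), and deduplicated on
    (patient_id, generic_name), keeping the first occurrence. Output order is
    stable. Records with an empty name after normalization are rejected with a
    warning rather than raising.
    """
    synonyms = synonyms or {}
    out: list = []
    seen: set = set()
    for rec in records:
        name = normalize_name(rec.raw_name)
        if not name:
            logger.warning(
                "rejecting medication record with empty name (patient %s, raw %r)",
                rec.patient_id, rec.raw_name,
            )
            continue
        generic = synonyms.get(name, name)
        key = (rec.patient_id, generic)
        if key in seen:
            continue
        seen.add(key)
        out.append(replace(rec, generic_name=generic))
    return out


def regular_med_count(patient: Patient) -> int:
    """Number of regular medications, excluding cancer/supportive records."""
    return len(patient.regular_records())


def polypharmacy_class(
    count: int,
    threshold_poly: int = POLYPHARMACY_THRESHOLD,
    threshold_excessive: int = EXCESSIVE_THRESHOLD,
) -> str:
    """Classify a regular-medication count: 'none' | 'polypharmacy' | 'excessive'.

    Excessive (>=10 by default) implies the polypharmacy indicator in
    prevalence tallies; this function returns the most severe class only.
    """
    if count < 0:
        raise ValueError(f"medication count must be nonnegative, got {count}")
    if count >= threshold_excessive:
        return "excessive"
    if count >= threshold_poly:
        return "polypharmacy"
    return "none"


def cohort_summary(cohort: Sequence[Patient]) -> CohortSummary:
    """Cohort-level medication-burden summary.

    Percentages are patient-level prevalences over the full cohort, half-up
    rounded to one decimal; the nonprescription share is over medication
    occurrences (OTC + complementary as a fraction of all regular occurrences).
    """
    if not cohort:
        raise ValueError("cohort is empty")
    counts = np.array([regular_med_count(p) for p in cohort])
    regular = [m for p in cohort for m in p.regular_records()]
    n_occ = len(regular)
    n_nonrx = sum(1 for m in regular if m.category in NONPRESCRIPTION_CATEGORIES)
    n_poly = int((counts >= POLYPHARMACY_THRESHOLD).sum())
    n_exc = int((counts >= EXCESSIVE_THRESHOLD).sum())
    return CohortSummary(
        n_patients=len(cohort),
        n_med_occurrences=n_occ,
        n_distinct_generics=len({m.generic_name for m in regular}),
        median_meds=float(np.median(counts)),
        range_meds=(int(counts.min()), int(counts.max())),
        pct_polypharmacy=pct(n_poly, len(cohort)),
        pct_excessive_polypharmacy=pct(n_exc, len(cohort)),
        pct_nonprescription_of_total=pct(n_nonrx, n_occ) if n_occ else 0.0,
    )


# ---------------------------------------------------------------------------
# CSV interfaces (UTF-8, comma-separated, header row)

def read_medication_log(path) -> list:
    """Read a medication log CSV into raw MedicationRecord objects.

    Columns: patient_id, drug_name, category, is_cancer_treatment,
    is_supportive_care. Booleans accept 0/1 or true/false.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            MedicationRecord(
                patient_id=str(row.patient_id),
                raw_name=row.drug_name,
                generic_name=row.drug_name.strip().lower(),
                category=row.category,
                is_cancer_treatment=_as_bool(row.is_cancer_treatment),
                is_supportive_care=_as_bool(row.is_supportive_care),
            )
        )
    return records


def write_medication_log(records: Iterable[MedicationRecord], path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "drug_name": r.raw_name,
            "category": r.category,
            "is_cancer_treatment": int(r.is_cancer_treatment),
            "is_supportive_care": int(r.is_supportive_care),
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "patient_id", "drug_name", "category",
            "is_cancer_treatment", "is_supportive_care",
        ],
    ).to_csv(path, index=False)


def read_synonyms(path) -> dict:
    """Two-column brand,generic CSV -> lowercase mapping."""
    df = pd.read_csv(path, dtype=str)
    return {
        str(b).strip().lower(): str(g).strip().lower()
        for b, g in zip(df["brand"], df["generic"])
    }


def _as_bool(x) -> bool:
    return str(x).strip().lower() in {"1", "true", "yes", "t"}


def assemble_patients(
    records: Sequence[MedicationRecord],
    covariates: pd.DataFrame,
    synonyms: Mapping[str, str] | None = None,
) -> list:
    """Join a normalized medication log onto a covariate table.

    ``covariates`` must carry patient_id and age_years; every other column is
    stored in the covariate map except ``ga_*`` flag columns, which populate
    the impairment set. Patients present in the covariate table but absent
    from the log get empty medication lists (a zero-medication patient is a
    real observation, not an error).
    """
    clean = normalize_and_dedupe(records, synonyms)
    by_patient: dict = {}
    for rec in clean:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    patients = []
    for row in covariates.to_dict("records"):
        pid = str(row.pop("patient_id"))
        age = int(row.pop("age_years"))
        ga = {
            k[len("ga_"):] for k, v in list(row.items())
            if k.startswith("ga_") and _as_bool(row.pop(k))
        }
        meds = by_patient.get(pid, [])
        patients.append(
            Patient(
                patient_id=pid,
                age_years=age,
                covariates={k: v for k, v in row.items() if not k.startswith("ga_")},
                ga_impairments=ga,
                regular_meds=[m for m in meds if m.is_regular],
                cancer_meds=[m for m in meds if not m.is_regular],
            )
        )
    return patients
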