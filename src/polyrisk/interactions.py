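"""Severity-graded drug-interaction detection.

The knowledge base holds unordered generic-name pairs with one of three
severities: C (monitor therapy), D (consider therapy modification), X (avoid
combination). D and X together are "major".

Two detection boundaries exist:
  * DDI — both members are regular medications (cancer-treatment and
    supportive-care drugs excluded from both sides);
  * DCI — exactly one member is a cancer-treatment drug (supportive-care
    drugs excluded entirely).

Matching is by generic name: interaction severity is substance-specific, so
the ATC hierarchy enters only downstream when detections are aggregated into
networks and chord matrices.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import pct

logger = logging.getLogger(__name__)

SEVERITIES = ("C", "D", "X")
_SEVERITY_RANK = {"C": 0, "D": 1, "X": 2}
MAJOR_SEVERITIES = frozenset({"D", "X"})


def canonical_pair(drug_a: str, drug_b: str) -> tuple:
    """Lexicographically ordered lowercase pair; identical drugs rejected."""
    a, b = sorted((drug_a.strip().lower(), drug_b.strip().lower()))
    if a == b:
        raise ValueError(f"interaction pair with identical drugs: {drug_a!r}")
    return a, b


@dataclass(frozen=True)
class InteractionEntry:
    drug_a: str
    drug_b: str
    severity: str

    def __post_init__(self) -> None:
        if self.severity not in SEVERITIES:
            raise ValueError(f"unknown interaction severity: {self.severity!r}")
        if not self.drug_a < self.drug_b:
            raise ValueError("interaction pair not in canonical order")

    @property
    def pair(self) -> tuple:
        return (self.drug_a, self.drug_b)


@dataclass(frozen=True)
class DetectedInteraction:
    patient_id: str
    pair: tuple
    severity: str
    kind: str  # "DDI" | "DCI"

    @property
    def major(self) -> bool:
        return self.severity in MAJOR_SEVERITIES


def build_kb(entries: Iterable[tuple]) -> dict:
    """Canonicalize (drug_a, drug_b, severity) triples into a pair->severity map.

    Duplicate pairs keep the maximum severity (X > D > C); the merge is logged.
    """
    kb: dict = {}
    for drug_a, drug_b, severity in entries:
        severity = str(severity).strip().upper()
        if severity not in SEVERITIES:
            raise ValueError(f"unknown interaction severity: {severity!r}")
        pair = canonical_pair(drug_a, drug_b)
        if pair in kb and kb[pair] != severity:
            kept = max(kb[pair], severity, key=_SEVERITY_RANK.__getitem__)
            logger.info(
                "duplicate KB pair %s: severities %s/%s merged to %s",
                pair, kb[pair], severity, kept,
            )
            kb[pair] = kept
        else:
            kb[pair] = severity
    return kb


def load_kb(path) -> dict:
    """Load a CSV knowledge base (drug_a, drug_b, severity)."""
    df = pd.read_csv(path, dtype=str)
    return build_kb(
        (r.drug_a, r.drug_b, r.severity) for r in df.itertuples(index=False)
    )


def find_ddi(patient, kb: Mapping[tuple, str]) -> list:
    """All regular-regular interactions for one patient.

    Every unordered pair of distinct regular medications is looked up once;
    each knowledge-base hit is emitted once per patient.
    """
    meds = sorted({m.generic_name for m in patient.regular_records()})
    out = []
    for a, b in itertools.combinations(meds, 2):
        severity = kb.get((a, b))
        if severity is not None:
            out.append(DetectedInteraction(patient.patient_id, (a, b), severity, "DDI"))
    return out


def find_dci(patient, kb: Mapping[tuple, str]) -> list:
    """Interactions across the regular x cancer-treatment boundary.

    Supportive-care drugs are excluded entirely; cancer drugs are never
    paired among themselves.
    """
    regular = sorted({m.generic_name for m in patient.regular_records()})
    cancer = sorted({m.generic_name for m in patient.cancer_treatment_records()})
    out = []
    for r in regular:
        for c in cancer:
            if r == c:
                continue
            pair = canonical_pair(r, c)
            severity = kb.get(pair)
            if severity is not None:
                out.append(
                    DetectedInteraction(patient.patient_id, pair, severity, "DCI")
                )
    return out


@dataclass(frozen=True)
class InteractionSummary:
    n_patients: int
    n_ddi: int
    n_ddi_by_severity: dict
    n_dci: int
    n_dci_by_severity: dict
    pct_any_ddi: float
    pct_ddi_by_severity: dict
    pct_major_ddi: float
    pct_any_dci: float
    pct_major_dci: float


def detect_cohort(cohort: Sequence, kb: Mapping[tuple, str]) -> list:
    """All DDI and DCI detections across a cohort (patient order preserved)."""
    out = []
    for patient in cohort:
        out.extend(find_ddi(patient, kb))
        out.extend(find_dci(patient, kb))
    return out


def interaction_summary(cohort: Sequence, kb: Mapping[tuple, str]) -> InteractionSummary:
    """Cohort-level interaction burden.

    Totals sum patient-level detections (a pair seen in k patients counts k
    occurrences); percentages are patient prevalences over the full cohort.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    n = len(cohort)
    ddi_by_sev = {s: 0 for s in SEVERITIES}
    dci_by_sev = {s: 0 for s in SEVERITIES}
    patients_sev = {s: 0 for s in SEVERITIES}
    any_ddi = major_ddi = any_dci = major_dci = 0
    for patient in cohort:
        ddi = find_ddi(patient, kb)
        dci = find_dci(patient, kb)
        for det in ddi:
            ddi_by_sev[det.severity] += 1
        for det in dci:
            dci_by_sev[det.severity] += 1
        for s in SEVERITIES:
            if any(d.severity == s for d in ddi):
                patients_sev[s] += 1
        any_ddi += bool(ddi)
        major_ddi += any(d.major for d in ddi)
        any_dci += bool(dci)
        major_dci += any(d.major for d in dci)
    return InteractionSummary(
        n_patients=n,
        n_ddi=sum(ddi_by_sev.values()),
        n_ddi_by_severity=ddi_by_sev,
        n_dci=sum(dci_by_sev.values()),
        n_dci_by_severity=dci_by_sev,
        pct_any_ddi=pct(any_ddi, n),
        pct_ddi_by_severity={s: pct(patients_sev[s], n) for s in SEVERITIES},
        pct_major_ddi=pct(major_ddi, n),
        pct_any_dci=pct(any_dci, n),
        pct_major_dci=pct(major_dci, n),
    )


def write_detections(detections: Iterable[DetectedInteraction], path) -> None:
    rows = [
        {
            "patient_id": d.patient_id,
            "drug_a": d.pair[0],
            "drug_b": d.pair[1],
            "severity": d.severity,
            "kind": d.kind,
            "major": int(d.major),
        }
        for d in detections
    ]
    pd.DataFrame(
        rows, columns=["patient_id", "drug_a", "drug_b", "severity", "kind", "major"]
    ).to_csv(path, index=False)
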