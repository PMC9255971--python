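"""Declarative screening for potentially inappropriate medications (PIMs).

A PIM criterion names the medications it targets (ATC prefixes and/or
explicit generic names, union semantics) and optional conjunctive patient
predicates (minimum age, a required covariate value, a required co-medication
ATC prefix, a required geriatric-assessment impairment). Rules come from two
catalogs — Beers-2019-style and STOPP-style — and the shipped ruleset is a
documented representative subset of each, not the licensed full catalogs.

A patient is PIM-positive for a source when at least one rule of that source
flags at least one of their regular medications; the union indicator counts
a patient once regardless of how many rules fire.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from ._util import pct
from .medlog import NONPRESCRIPTION_CATEGORIES

logger = logging.getLogger(__name__)

SOURCES = ("BEERS2019", "STOPP")


@dataclass(frozen=True)
class PIMRule:
    rule_id: str
    source: str
    target_atc: tuple = ()
    target_generic: tuple = ()
    min_age: int | None = None
    required_covariates: tuple = ()  # ((key, value), ...)
    required_co_medication_atc: str | None = None
    required_ga_flag: str | None = None
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"rule {self.rule_id}: unknown source {self.source!r}")
        if not (self.target_atc or self.target_generic):
            raise ValueError(f"rule {self.rule_id}: empty target set")


@dataclass(frozen=True)
class PIMFlag:
    patient_id: str
    rule_id: str
    source: str
    generic_name: str
    category: str


def load_ruleset(path) -> list:
    """Load and validate a JSON ruleset.

    Schema: array of objects with rule_id, source, targets {atc: [...],
    generic: [...]}, optional predicates {min_age, covariates {k: v},
    co_medication_atc, ga_flag}, rationale. Duplicate rule_id or schema
    violations raise; an empty file yields an empty ruleset with a warning.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if not raw:
        logger.warning("ruleset %s is empty", path)
        return []
    rules = []
    seen = set()
    for obj in raw:
        rule_id = obj.get("rule_id", "")
        if rule_id in seen:
            raise ValueError(f"duplicate rule_id: {rule_id}")
        seen.add(rule_id)
        targets = obj.get("targets", {})
        pred = obj.get("predicates", {}) or {}
        rules.append(
            PIMRule(
                rule_id=rule_id,
                source=obj.get("source", ""),
                target_atc=tuple(t.upper() for t in targets.get("atc", [])),
                target_generic=tuple(
                    t.strip().lower() for t in targets.get("generic", [])
                ),
                min_age=pred.get("min_age"),
                required_covariates=tuple(
                    sorted((k, str(v)) for k, v in (pred.get("covariates") or {}).items())
                ),
                required_co_medication_atc=pred.get("co_medication_atc"),
                required_ga_flag=pred.get("ga_flag"),
                rationale=obj.get("rationale", ""),
            )
        )
    return rules


def _med_codes(generic: str, formulary: Mapping) -> tuple:
    entry = formulary.get(generic)
    return entry.atc_codes if entry is not None else ()


def _rule_matches_med(rule: PIMRule, generic: str, formulary: Mapping) -> bool:
    if generic in rule.target_generic:
        return True
    codes = _med_codes(generic, formulary)
    return any(code.startswith(prefix) for code in codes for prefix in rule.target_atc)


def _predicates_hold(rule: PIMRule, patient, formulary: Mapping) -> bool:
    """Conjunctive predicate evaluation; missing covariates fail closed."""
    if rule.min_age is not None and patient.age_years < rule.min_age:
        return False
    for key, value in rule.required_covariates:
        if key not in patient.covariates:
            logger.warning(
                "patient %s missing covariate %r needed by rule %s; predicate fails closed",
                patient.patient_id, key, rule.rule_id,
            )
            return False
        if str(patient.covariates[key]) != value:
            return False
    if rule.required_ga_flag is not None:
        if rule.required_ga_flag not in patient.ga_impairments:
            return False
    if rule.required_co_medication_atc is not None:
        prefix = rule.required_co_medication_atc
        if not any(
            code.startswith(prefix)
            for med in patient.regular_records()
            for code in _med_codes(med.generic_name, formulary)
        ):
            return False
    return True


def screen_patient(patient, rules: Sequence[PIMRule], formulary: Mapping) -> list:
    """One flag per (rule, matching regular medication) with all predicates true.

    Output is sorted by (rule_id, generic_name) so screening is deterministic.
    A drug is matched against every ATC code the formulary lists for it, since
    class-based criteria apply to any class the substance belongs to.
    """
    flags = []
    for rule in rules:
        if not _predicates_hold(rule, patient, formulary):
            continue
        for med in patient.regular_records():
            if _rule_matches_med(rule, med.generic_name, formulary):
                flags.append(
                    PIMFlag(
                        patient_id=patient.patient_id,
                        rule_id=rule.rule_id,
                        source=rule.source,
                        generic_name=med.generic_name,
                        category=med.category,
                    )
                )
    flags.sort(key=lambda f: (f.rule_id, f.generic_name))
    return flags


@dataclass(frozen=True)
class PIMPrevalence:
    n_patients: int
    pct_by_source: dict            # source -> % patients with >=1 flag
    pct_union: float               # % patients flagged by either catalog
    per_patient_flag_counts: dict  # patient_id -> total flags
    nonrx_share_of_flags: dict     # source -> % of flags on OTC/complementary meds
    n_flags_by_source: dict


def pim_prevalence(
    cohort: Sequence, rules: Sequence[PIMRule], formulary: Mapping
) -> tuple:
    """Cohort PIM prevalence by catalog and union, plus all flags.

    Returns ``(PIMPrevalence, flags)``. Prevalence counts a patient once per
    source however many rules fire; the nonprescription share is computed
    over flags (flagged-medication occurrences), per source.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    n = len(cohort)
    flagged_patients = {s: set() for s in SOURCES}
    union_patients: set = set()
    flag_counts: dict = {}
    all_flags: list = []
    n_flags = {s: 0 for s in SOURCES}
    n_nonrx = {s: 0 for s in SOURCES}
    for patient in cohort:
        flags = screen_patient(patient, rules, formulary)
        all_flags.extend(flags)
        flag_counts[patient.patient_id] = len(flags)
        for f in flags:
            flagged_patients[f.source].add(patient.patient_id)
            union_patients.add(patient.patient_id)
            n_flags[f.source] += 1
            if f.category in NONPRESCRIPTION_CATEGORIES:
                n_nonrx[f.source] += 1
    prev = PIMPrevalence(
        n_patients=n,
        pct_by_source={s: pct(len(flagged_patients[s]), n) for s in SOURCES},
        pct_union=pct(len(union_patients), n),
        per_patient_flag_counts=flag_counts,
        nonrx_share_of_flags={
            s: pct(n_nonrx[s], n_flags[s]) if n_flags[s] else 0.0 for s in SOURCES
        },
        n_flags_by_source=n_flags,
    )
    return prev, all_flags


def class_breakdown(
    flags: Sequence[PIMFlag], cohort: Sequence, formulary: Mapping, level: int = 2
) -> pd.DataFrame:
    """Flagged-medication classes under both denominators.

    The share of e.g. proton-pump-inhibitor PIMs can be quoted per patient
    (patients with >=1 such flag / cohort n) or per flag (such flags / all
    flags); both are reported, labeled, since published summaries rarely say
    which they use.
    """
    from .atc import rollup

    n = len(cohort)
    rows = []
    if not flags:
        return pd.DataFrame(
            columns=["atc_class", "n_flags", "pct_of_flags", "n_patients", "pct_of_patients"]
        )
    per_class_flags: dict = {}
    per_class_patients: dict = {}
    for f in flags:
        entry = formulary.get(f.generic_name)
        label = rollup(entry.primary_code, level) if entry else "unclassified"
        per_class_flags[label] = per_class_flags.get(label, 0) + 1
        per_class_patients.setdefault(label, set()).add(f.patient_id)
    total = len(flags)
    for label in sorted(per_class_flags, key=per_class_flags.get, reverse=True):
        rows.append(
            {
                "atc_class": label,
                "n_flags": per_class_flags[label],
                "pct_of_flags": pct(per_class_flags[label], total),
                "n_patients": len(per_class_patients[label]),
                "pct_of_patients": pct(len(per_class_patients[label]), n),
            }
        )
    return pd.DataFrame(rows)


def write_flags(flags: Sequence[PIMFlag], path) -> None:
    rows = [
        {
            "patient_id": f.patient_id,
            "rule_id": f.rule_id,
            "source": f.source,
            "generic_name": f.generic_name,
            "category": f.category,
        }
        for f in flags
    ]
    pd.DataFrame(
        rows, columns=["patient_id", "rule_id", "source", "generic_name", "category"]
    ).to_csv(path, index=False)
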