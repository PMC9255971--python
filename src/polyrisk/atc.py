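"""WHO ATC classification: code validation, level rollups, cohort annotation.

An ATC code is a 7-character string with five nested levels, e.g. C10AA05
(atorvastatin): C = cardiovascular system (level 1), C10 = lipid modifying
agents (level 2), C10A (level 3), C10AA (level 4), C10AA05 (level 5,
chemical substance). Level prefixes have lengths 1, 3, 4, 5 and 7.

The formulary maps each generic name to one or more ATC codes with a
designated primary code; class tallies and network node assignment use the
primary code only, so each occurrence lands in exactly one subgroup.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

_ATC_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")
_LEVEL_LEN = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}

MEDICATION_LEVEL = "medication"  # sentinel: no rollup, node = generic name


class ATCFormatError(ValueError):
    pass


def parse_atc(code: str) -> str:
    """Validate and case-normalize a full 7-character ATC code."""
    norm = str(code).strip().upper()
    if not _ATC_RE.match(norm):
        raise ATCFormatError(f"not a valid ATC code: {code!r}")
    return norm


def rollup(code: str, level: int) -> str:
    """Prefix of ``code`` at the requested level (1-5)."""
    if level not in _LEVEL_LEN:
        raise ValueError(f"ATC level must be 1-5, got {level}")
    return parse_atc(code)[: _LEVEL_LEN[level]]


@dataclass(frozen=True)
class FormularyEntry:
    generic_name: str
    atc_codes: tuple
    primary_index: int = 0

    def __post_init__(self) -> None:
        if not self.atc_codes:
            raise ValueError(f"{self.generic_name}: empty ATC code list")
        if not 0 <= self.primary_index < len(self.atc_codes):
            raise ValueError(f"{self.generic_name}: primary_index out of range")

    @property
    def primary_code(self) -> str:
        return self.atc_codes[self.primary_index]


def load_formulary(path) -> dict:
    """Load a formulary CSV (generic_name, atc_codes ';'-separated, primary_index).

    Returns a dict keyed by lowercase generic name.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    formulary: dict = {}
    for row in df.itertuples(index=False):
        name = row.generic_name.strip().lower()
        codes = tuple(parse_atc(c) for c in row.atc_codes.split(";") if c.strip())
        idx = int(row.primary_index) if str(row.primary_index).strip() else 0
        if name in formulary:
            raise ValueError(f"duplicate formulary entry: {name}")
        formulary[name] = FormularyEntry(name, codes, idx)
    return formulary


def write_formulary(formulary: Mapping[str, FormularyEntry], path) -> None:
    rows = [
        {
            "generic_name": e.generic_name,
            "atc_codes": ";".join(e.atc_codes),
            "primary_index": e.primary_index,
        }
        for e in formulary.values()
    ]
    pd.DataFrame(rows, columns=["generic_name", "atc_codes", "primary_index"]).to_csv(
        path, index=False
    )


def classify_cohort(cohort: Sequence, formulary: Mapping[str, FormularyEntry]):
    """Annotate every regular-medication occurrence with ATC level-1..3 prefixes.

    Returns ``(assignments, unclassified)``: ``assignments`` has one row per
    regular occurrence (patient_id, generic_name, category, atc, level1-3;
    ATC columns empty for unmapped generics), ``unclassified`` aggregates
    unmapped generics with occurrence counts. Unclassified occurrences stay in
    medication counts but are excluded from class tallies.
    """
    rows = []
    for patient in cohort:
        for med in patient.regular_records():
            entry = formulary.get(med.generic_name)
            if entry is None:
                rows.append(
                    {
                        "patient_id": patient.patient_id,
                        "generic_name": med.generic_name,
                        "category": med.category,
                        "atc": "",
                        "level1": "",
                        "level2": "",
                        "level3": "",
                    }
                )
            else:
                code = entry.primary_code
                rows.append(
                    {
                        "patient_id": patient.patient_id,
                        "generic_name": med.generic_name,
                        "category": med.category,
                        "atc": code,
                        "level1": rollup(code, 1),
                        "level2": rollup(code, 2),
                        "level3": rollup(code, 3),
                    }
                )
    assignments = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "generic_name", "category",
            "atc", "level1", "level2", "level3",
        ],
    )
    if len(assignments):
        unmapped = assignments[assignments["atc"] == ""]
        unclassified = (
            unmapped.groupby("generic_name").size().rename("occurrence_count")
            .reset_index().sort_values(
                ["occurrence_count", "generic_name"], ascending=[False, True]
            ).reset_index(drop=True)
        )
    else:
        unclassified = pd.DataFrame(columns=["generic_name", "occurrence_count"])
    return assignments, unclassified


def level_tally(assignments: pd.DataFrame, level: int) -> pd.Series:
    """Occurrence counts per ATC class at the given level (classified rows only)."""
    col = f"level{level}"
    if col not in assignments.columns:
        raise ValueError(f"no annotation column for level {level}")
    classified = assignments[assignments["atc"] != ""]
    return classified.groupby(col).size().sort_values(ascending=False)


def annotation_map(
    formulary: Mapping[str, FormularyEntry], level
) -> dict:
    """generic name -> node label at ``level`` (primary-code rollup).

    At ``MEDICATION_LEVEL`` the label is the generic name itself.
    """
    if level == MEDICATION_LEVEL:
        return {name: name for name in formulary}
    return {
        name: rollup(entry.primary_code, int(level))
        for name, entry in formulary.items()
    }
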