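"""Access to packaged fixtures and published reference counts.

``load_reference_tables`` exposes the headline counts and the bivariate 2x2
tables transcribed from the published geriatric-oncology cohort (n = 718)
this package re-implements; they serve as desk-scale inputs for recomputing
published percentages and prevalence odds ratios. ``packaged_*`` helpers
return the curated mini-formulary, synonym table, PIM ruleset, and
interaction knowledge base shipped with the package.
"""

from __future__ import annotations

import json
from importlib import resources

from . import atc, interactions, medlog, pim

_DATA = resources.files("polyrisk") / "data"


def _path(name: str):
    # editable/installed layouts both expose data/ as a real directory
    with resources.as_file(_DATA / name) as p:
        return p


def load_reference_tables() -> dict:
    """Published cohort counts and association rows (see data/reference_tables.json)."""
    with _path("reference_tables.json").open() as fh:
        return json.load(fh)


def packaged_formulary() -> dict:
    return atc.load_formulary(_path("formulary.csv"))


def packaged_synonyms() -> dict:
    return medlog.read_synonyms(_path("synonyms.csv"))


def packaged_ruleset() -> list:
    return pim.load_ruleset(_path("pim_rules.json"))


def packaged_kb() -> dict:
    return interactions.load_kb(_path("interactions_kb.csv"))


def packaged_drug_pools() -> dict:
    with _path("drug_pools.json").open() as fh:
        return json.load(fh)
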