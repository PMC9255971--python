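"""Synthetic geriatric-oncology cohort generator with a planted-truth ledger.

Emulates the study conditions of a ~718-patient cohort of adults aged >= 70
with advanced cancer starting systemic treatment: per-patient regular
medication counts with median 5 (range clamped to 0-24) drawn from a
negative binomial riding a latent log-normal frailty; a ~73/27
prescription/nonprescription occurrence split with cardiovascular agents the
dominant prescription class; covariate marginals matching the published
baseline table; and planted, recoverable effects — the odds of the planted
major-interaction outcome rising 39%/12% per additional medication, and a
comorbidity-polypharmacy prevalence odds ratio of 3.4.

Every generated cohort ships with a :class:`PlantedTruth` recording the true
parameter values used, sufficient to score recovery end-to-end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import reference
from .atc import rollup, write_formulary
from .medlog import MedicationRecord, Patient, write_medication_log

CATEGORY_ORDER = ("prescription", "otc", "complementary")

#: Covariate category distributions (normalized at draw time), following the
#: published baseline marginals of the emulated cohort.
DEFAULT_COVARIATE_PREVALENCES: dict = {
    "age_band": {"70-74": 0.377, "75-79": 0.313, ">=80": 0.310},
    "gender": {"male": 0.564, "female": 0.436},
    "race": {"white": 0.875, "black": 0.072, "others": 0.049},
    "education": {"< high school": 0.155, "high school": 0.340, "college or above": 0.503},
    "income": {"<=50k": 0.517, ">50k": 0.265, "declined": 0.216},
    "marital_status": {"single": 0.024, "married": 0.625, "separated/widowed/divorced": 0.348},
    "cancer_type": {
        "gastrointestinal": 0.342, "lung": 0.251, "genitourinary": 0.152,
        "breast": 0.078, "lymphoma": 0.064, "gynecological": 0.060, "others": 0.053,
    },
    "stage": {"III": 0.125, "IV": 0.875},
    "treatment_line": {"first": 0.70, "second or later": 0.30},
    "life_expectancy": {"<=12 months": 0.335, ">12 months": 0.665},
    "kps": {"20-60": 0.130, "70-80": 0.528, "90-100": 0.339},
}

#: Geriatric-assessment impairment planting: domain -> (probability when not
#: polypharmacy, odds ratio for polypharmacy). Domains with OR 1.0 are
#: unconditioned background prevalences.
DEFAULT_GA_EFFECTS: dict = {
    "comorbidity": (0.507, 3.4),
    "function": (0.500, 1.64),
    "physical": (0.901, 2.0),
    "psychological": (0.219, 1.73),
    "cognition": (0.25, 1.0),
    "social": (0.35, 1.0),
    "nutrition": (0.50, 1.0),
}

DEFAULT_PLANTED_EFFECTS: dict = {
    "or_major_ddi_per_med": 1.39,
    "or_major_dci_per_med": 1.12,
    "target_prevalence_major_ddi": 0.247,
    "target_prevalence_major_dci": 0.054,
}

#: Target ATC level-2 occurrence shares within a category pool; classes not
#: listed split the remaining mass uniformly per drug.
_PRESCRIPTION_CLASS_SHARES = {"C10": 0.130, "C09": 0.095, "C07": 0.095, "A10": 0.072, "C03": 0.066}
_NONRX_CLASS_SHARES = {"A11": 0.270, "B03": 0.149, "A02": 0.146, "A12": 0.098}

#: Cancer regimens by cancer type (drug names resolve in the formulary).
_REGIMENS: dict = {
    "gastrointestinal": [
        ["oxaliplatin", "fluorouracil"], ["capecitabine", "oxaliplatin"],
        ["gemcitabine"], ["fluorouracil", "irinotecan"],
    ],
    "lung": [
        ["carboplatin", "paclitaxel"], ["carboplatin", "pemetrexed"],
        ["pembrolizumab"], ["cisplatin", "etoposide"], ["erlotinib"],
    ],
    "genitourinary": [
        ["abiraterone"], ["enzalutamide"], ["carboplatin", "gemcitabine"], ["docetaxel"],
    ],
    "gynecological": [["carboplatin", "paclitaxel"], ["carboplatin", "docetaxel"]],
    "breast": [["letrozole"], ["capecitabine"], ["paclitaxel"], ["tamoxifen"]],
    "lymphoma": [
        ["rituximab"], ["rituximab", "cyclophosphamide", "doxorubicin"],
        ["rituximab", "cyclophosphamide", "etoposide"],
    ],
    "others": [["carboplatin", "paclitaxel"], ["nivolumab"], ["gemcitabine"]],
}


@dataclass
class SyntheticConfig:
    """Generator configuration; ``seed`` is mandatory for full determinism."""

    seed: int
    n_patients: int = 718
    med_count_dispersion: float = 5.0   # negative-binomial size parameter r
    med_count_mean: float = 6.0         # marginal mean before clamping
    med_count_max: int = 24
    frailty_sd: float = 0.20            # log-scale spread of per-patient means
    category_mix: tuple = (0.733, 0.187, 0.080)  # prescription/otc/complementary
    kb_size: int | None = None          # None -> curated packaged KB
    kb_severity_mix: tuple = (0.86, 0.12, 0.02)  # C, D, X
    covariate_prevalences: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_PREVALENCES.items()}
    )
    ga_effects: dict = field(default_factory=lambda: dict(DEFAULT_GA_EFFECTS))
    planted_effects: dict = field(default_factory=lambda: dict(DEFAULT_PLANTED_EFFECTS))

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for mix, name in ((self.category_mix, "category_mix"),
                          (self.kb_severity_mix, "kb_severity_mix")):
            if any(not 0 <= p <= 1 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be probabilities summing to 1")
        if self.med_count_dispersion <= 0 or self.med_count_mean <= 0:
            raise ValueError("medication-count parameters must be positive")


@dataclass
class PlantedTruth:
    """True parameter values used during generation, for recovery scoring."""

    seed: int
    effects: dict
    med_counts: list
    outcomes: dict  # {"major_ddi": [...], "major_dci": [...]}

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "effects": self.effects,
                "med_counts": self.med_counts,
                "outcomes": self.outcomes,
            },
            indent=1,
        )


@dataclass
class SyntheticFixtures:
    formulary: dict
    kb: dict
    ruleset: list
    synonyms: dict
    pools: dict


def generate_formulary(config: SyntheticConfig, rng: np.random.Generator | None = None) -> SyntheticFixtures:
    """Internally consistent formulary + interaction KB + PIM ruleset trio.

    The formulary, synonym table and ruleset are the curated packaged
    fixtures. The knowledge base is either the curated one (``kb_size is
    None``) or ``kb_size`` random distinct formulary pairs with severities
    drawn from ``kb_severity_mix``. Every KB drug and every explicit rule
    target resolves in the formulary.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    formulary = reference.packaged_formulary()
    ruleset = reference.packaged_ruleset()
    pools = reference.packaged_drug_pools()
    if config.kb_size is None:
        kb = reference.packaged_kb()
    else:
        names = sorted(set(formulary) )
        kb = {}
        sev = np.array(["C", "D", "X"])
        while len(kb) < config.kb_size:
            a, b = rng.choice(len(names), size=2, replace=False)
            pair = tuple(sorted((names[a], names[b])))
            if pair not in kb:
                kb[pair] = str(rng.choice(sev, p=list(config.kb_severity_mix)))
    fixtures = SyntheticFixtures(
        formulary=formulary,
        kb=kb,
        ruleset=ruleset,
        synonyms=reference.packaged_synonyms(),
        pools=pools,
    )
    _check_integrity(fixtures)
    return fixtures


def _check_integrity(fx: SyntheticFixtures) -> None:
    unresolved_kb = {
        d for pair in fx.kb for d in pair if d not in fx.formulary
    }
    if unresolved_kb:
        raise ValueError(f"KB drugs missing from formulary: {sorted(unresolved_kb)}")
    for rule in fx.ruleset:
        missing = [g for g in rule.target_generic if g not in fx.formulary]
        if missing:
            raise ValueError(f"rule {rule.rule_id} targets unknown generics: {missing}")


def _pool_weights(names: list, formulary: dict, class_shares: dict) -> np.ndarray:
    """Per-drug sampling weights hitting target level-2 class shares."""
    level2 = {
        n: rollup(formulary[n].primary_code, 2) if n in formulary else None
        for n in names
    }
    class_members: dict = {}
    for n, lv in level2.items():
        class_members.setdefault(lv, []).append(n)
    targeted = {c: s for c, s in class_shares.items() if c in class_members}
    rest_mass = 1.0 - sum(targeted.values())
    rest = [n for n in names if level2[n] not in targeted]
    w = np.empty(len(names))
    for i, n in enumerate(names):
        lv = level2[n]
        if lv in targeted:
            w[i] = targeted[lv] / len(class_members[lv])
        else:
            w[i] = rest_mass / len(rest)
    return w / w.sum()


def sample_med_counts(rng: np.random.Generator, config: SyntheticConfig, n: int | None = None) -> np.ndarray:
    """Clamped negative-binomial medication counts with log-normal frailty.

    Per-patient mean mu_i = mean * exp(z_i - sd^2/2), z_i ~ N(0, sd^2), so the
    marginal mean is preserved while frail patients carry heavier burdens.
    """
    n = n if n is not None else config.n_patients
    z = rng.normal(0.0, config.frailty_sd, n)
    mu = config.med_count_mean * np.exp(z - config.frailty_sd**2 / 2)
    r = config.med_count_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    return np.clip(counts, 0, config.med_count_max)


def sample_planted_outcome(
    rng: np.random.Generator, counts: np.ndarray, odds_ratio: float, target_prevalence: float
) -> tuple:
    """Binary outcome via a logistic link on medication count.

    The intercept anchors the linear predictor so the outcome prevalence at
    the mean count equals ``target_prevalence``. Returns ``(y, intercept)``.
    """
    slope = math.log(odds_ratio)
    intercept = math.log(target_prevalence / (1 - target_prevalence)) - slope * counts.mean()
    p = 1.0 / (1.0 + np.exp(-(intercept + slope * counts)))
    return (rng.random(len(counts)) < p).astype(int), intercept


def _draw_categorical(rng, table: dict) -> str:
    keys = list(table)
    p = np.array([table[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


_AGE_RANGES = {"70-74": (70, 74), "75-79": (75, 79), ">=80": (80, 96)}


def generate_cohort(
    config: SyntheticConfig, fixtures: SyntheticFixtures | None = None
) -> tuple:
    """Generate ``(patients, truth)`` under the configured study conditions.

    Deterministic under a fixed seed and config. Planted structure:

    * comorbidity (and other GA-domain) impairment probabilities conditioned
      on the patient's polypharmacy indicator at the configured odds ratios;
    * binary major-DDI/DCI outcomes drawn from a logistic link on the
      medication count at the configured per-medication odds ratios, recorded
      in :class:`PlantedTruth` for recovery scoring.
    """
    rng = np.random.default_rng(config.seed)
    fixtures = fixtures if fixtures is not None else generate_formulary(config, rng)
    formulary, pools = fixtures.formulary, fixtures.pools

    otc = sorted(pools["otc"])
    complementary = sorted(pools["complementary"])
    cancer_pool = set(pools["cancer"])
    supportive = sorted(pools["supportive"])
    nonregular = cancer_pool | set(supportive)
    prescription = sorted(
        n for n in formulary
        if n not in nonregular and n not in otc and n not in complementary
    )
    pool_names = {
        "prescription": prescription,
        "otc": otc,
        "complementary": complementary,
    }
    pool_weights = {
        "prescription": _pool_weights(prescription, formulary, _PRESCRIPTION_CLASS_SHARES),
        "otc": _pool_weights(otc, formulary, _NONRX_CLASS_SHARES),
        "complementary": _pool_weights(complementary, formulary, {}),
    }

    counts = sample_med_counts(rng, config)
    cat_mix = np.asarray(config.category_mix, dtype=float)

    patients = []
    for i in range(config.n_patients):
        pid = f"P{i+1:04d}"
        band = _draw_categorical(rng, config.covariate_prevalences["age_band"])
        lo, hi = _AGE_RANGES[band]
        age = int(rng.integers(lo, hi + 1))
        covs = {"age_band": band}
        for var, table in config.covariate_prevalences.items():
            if var == "age_band":
                continue
            covs[var] = _draw_categorical(rng, table)

        # regular medications: category per occurrence, drug sampled without
        # replacement within the category pool (union fallback when exhausted)
        used: set = set()
        regular = []
        for _ in range(int(counts[i])):
            cat = CATEGORY_ORDER[rng.choice(3, p=cat_mix)]
            names, weights = pool_names[cat], pool_weights[cat]
            avail = [j for j, n in enumerate(names) if n not in used]
            if not avail:
                spare = [
                    n for c in CATEGORY_ORDER for n in pool_names[c] if n not in used
                ]
                if not spare:
                    break
                name = spare[rng.choice(len(spare))]
                cat = next(c for c in CATEGORY_ORDER if name in pool_names[c])
            else:
                w = weights[avail] / weights[avail].sum()
                name = names[avail[rng.choice(len(avail), p=w)]]
            used.add(name)
            regular.append(
                MedicationRecord(pid, name, name, cat)
            )

        regimen = _REGIMENS[covs["cancer_type"]]
        cancer_meds = [
            MedicationRecord(pid, n, n, "prescription", is_cancer_treatment=True)
            for n in regimen[rng.choice(len(regimen))]
        ]
        n_support = int(rng.choice(3, p=[0.30, 0.45, 0.25]))
        for j in rng.choice(len(supportive), size=n_support, replace=False):
            cancer_meds.append(
                MedicationRecord(
                    pid, supportive[j], supportive[j], "prescription",
                    is_supportive_care=True,
                )
            )

        poly = counts[i] >= 5
        ga = set()
        for domain, (p0, odds_ratio) in config.ga_effects.items():
            odds = p0 / (1 - p0) * (odds_ratio if poly else 1.0)
            if rng.random() < odds / (1 + odds):
                ga.add(domain)

        patients.append(
            Patient(
                patient_id=pid,
                age_years=age,
                covariates=covs,
                ga_impairments=ga,
                regular_meds=regular,
                cancer_meds=cancer_meds,
            )
        )

    eff = config.planted_effects
    y_ddi, a_ddi = sample_planted_outcome(
        rng, counts, eff["or_major_ddi_per_med"], eff["target_prevalence_major_ddi"]
    )
    y_dci, a_dci = sample_planted_outcome(
        rng, counts, eff["or_major_dci_per_med"], eff["target_prevalence_major_dci"]
    )
    truth = PlantedTruth(
        seed=config.seed,
        effects={
            "or_major_ddi_per_med": eff["or_major_ddi_per_med"],
            "or_major_dci_per_med": eff["or_major_dci_per_med"],
            "intercept_major_ddi": a_ddi,
            "intercept_major_dci": a_dci,
            "or_ga_polypharmacy": {d: o for d, (_, o) in config.ga_effects.items()},
            "ga_base_prevalence": {d: p for d, (p, _) in config.ga_effects.items()},
        },
        med_counts=[int(c) for c in counts],
        outcomes={"major_ddi": y_ddi.tolist(), "major_dci": y_dci.tolist()},
    )
    return patients, truth


# ---------------------------------------------------------------------------
# fixture and cohort writers (exact dialects the other modules consume)

def write_fixtures(fixtures: SyntheticFixtures, outdir) -> dict:
    """Write formulary/KB/ruleset/synonyms; returns the path map."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "formulary": outdir / "formulary.csv",
        "kb": outdir / "interactions_kb.csv",
        "ruleset": outdir / "pim_rules.json",
        "synonyms": outdir / "synonyms.csv",
    }
    write_formulary(fixtures.formulary, paths["formulary"])
    pd.DataFrame(
        [{"drug_a": a, "drug_b": b, "severity": s} for (a, b), s in sorted(fixtures.kb.items())],
        columns=["drug_a", "drug_b", "severity"],
    ).to_csv(paths["kb"], index=False)
    with open(paths["ruleset"], "w") as fh:
        json.dump(
            [
                {
                    "rule_id": r.rule_id,
                    "source": r.source,
                    "targets": {"atc": list(r.target_atc), "generic": list(r.target_generic)},
                    "predicates": {
                        k: v
                        for k, v in (
                            ("min_age", r.min_age),
                            ("covariates", dict(r.required_covariates) or None),
                            ("co_medication_atc", r.required_co_medication_atc),
                            ("ga_flag", r.required_ga_flag),
                        )
                        if v
                    },
                    "rationale": r.rationale,
                }
                for r in fixtures.ruleset
            ],
            fh,
            indent=1,
        )
    pd.DataFrame(
        sorted(fixtures.synonyms.items()), columns=["brand", "generic"]
    ).to_csv(paths["synonyms"], index=False)
    return paths


GA_DOMAINS = ("function", "physical", "comorbidity", "cognition", "social", "psychological", "nutrition")


def write_cohort(patients, truth: PlantedTruth, outdir) -> dict:
    """Write medication log, covariate table, and planted-truth JSON."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "medlog": outdir / "medication_log.csv",
        "covariates": outdir / "covariates.csv",
        "truth": outdir / "planted_truth.json",
    }
    records = [m for p in patients for m in (p.regular_meds + p.cancer_meds)]
    write_medication_log(records, paths["medlog"])
    rows = []
    for p in patients:
        row = {"patient_id": p.patient_id, "age_years": p.age_years, **p.covariates}
        for d in GA_DOMAINS:
            row[f"ga_{d}"] = int(d in p.ga_impairments)
        rows.append(row)
    pd.DataFrame(rows).to_csv(paths["covariates"], index=False)
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json())
    return paths
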