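#!/usr/bin/env python
"""Run the full medication-risk pipeline on the simulated cohort.

Consumes results/synthetic/ (from 01_simulate_cohort.py) and writes the
report bundle — cohort summary, PIM prevalence, interaction summary,
network metrics per level, chord matrices, association tables — under
results/pipeline/.
"""

import json
import pathlib

from polyrisk.pipeline import RunConfig, run_pipeline

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
SRC = ROOT / "synthetic"

config = RunConfig(
    medlog=SRC / "medication_log.csv",
    covariates=SRC / "covariates.csv",
    formulary=SRC / "formulary.csv",
    ruleset=SRC / "pim_rules.json",
    kb=SRC / "interactions_kb.csv",
    synonyms=SRC / "synonyms.csv",
    outdir=ROOT / "pipeline",
    seed=20240718,
)
manifest = run_pipeline(config)

out = ROOT / "pipeline"
summary = json.loads((out / "cohort_summary.json").read_text())
pim = json.loads((out / "pim_prevalence.json").read_text())
inter = json.loads((out / "interaction_summary.json").read_text())
net = json.loads((out / "network_metrics.json").read_text())

print("pipeline stages:", ", ".join(f"{k}={v}" for k, v in manifest["stages"].items()))
print(f"cohort: {summary['n_patients']} patients, {summary['n_med_occurrences']} occurrences "
      f"of {summary['n_distinct_generics']} generics; "
      f"polypharmacy {summary['pct_polypharmacy']}%, excessive {summary['pct_excessive_polypharmacy']}%")
print(f"PIM: Beers {pim['pct_by_source']['BEERS2019']}%, STOPP {pim['pct_by_source']['STOPP']}%, "
      f"union {pim['pct_union']}%; nonprescription share of flags {pim['nonrx_share_of_flags']}")
print(f"interactions: {inter['n_ddi']} DDI ({inter['n_ddi_by_severity']}), "
      f"{inter['n_dci']} DCI; major DDI in {inter['pct_major_ddi']}% of patients, "
      f"major DCI in {inter['pct_major_dci']}%")
m2 = net["2"]
print(f"ATC level-2 network: {m2['n_nodes']} nodes, {m2['n_edges']} edges, "
      f"density {m2['density']:.2f}, diameter {m2['diameter']}, "
      f"triadic closure {m2['triadic_closure']:.2f}")
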