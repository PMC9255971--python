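#!/usr/bin/env python
"""Generate the synthetic study cohort and its fixture files.

Writes a 718-patient cohort (medication log, covariate table, planted-truth
ledger) plus the formulary / interaction knowledge base / PIM ruleset it
resolves against, under results/synthetic/.
"""

import pathlib

import numpy as np

from polyrisk.medlog import regular_med_count
from polyrisk.synthetic import SyntheticConfig, generate_cohort, generate_formulary, write_cohort, write_fixtures

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20240718

config = SyntheticConfig(seed=SEED)
fixtures = generate_formulary(config)
cohort, truth = generate_cohort(config, fixtures)

paths = write_fixtures(fixtures, OUT)
paths.update(write_cohort(cohort, truth, OUT))

counts = np.array([regular_med_count(p) for p in cohort])
print(f"generated {len(cohort)} patients (seed {SEED})")
print(f"  regular medications: median {np.median(counts):.0f}, range {counts.min()}-{counts.max()}")
print(f"  polypharmacy (>=5): {100 * (counts >= 5).mean():.1f}%  excessive (>=10): {100 * (counts >= 10).mean():.1f}%")
print(f"  knowledge base: {len(fixtures.kb)} pairs, ruleset: {len(fixtures.ruleset)} rules")
for k, v in paths.items():
    print(f"  wrote {k}: {v}")
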