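[
  {
    "rule_id": "BEERS-PPI",
    "source": "BEERS2019",
    "targets": {"atc": ["A02BC"]},
    "rationale": "Proton pump inhibitors: risk of C. difficile infection, bone loss and fractures with sustained use in older adults."
  },
  {
    "rule_id": "BEERS-BZD",
    "source": "BEERS2019",
    "targets": {"atc": ["N05BA", "N05CD", "N03AE"]},
    "rationale": "Benzodiazepines: increased sensitivity and decreased clearance in older adults; cognitive impairment, delirium, falls, fractures."
  },
  {
    "rule_id": "BEERS-ZDRUG",
    "source": "BEERS2019",
    "targets": {"atc": ["N05CF"]},
    "rationale": "Benzodiazepine-receptor-agonist hypnotics: adverse events similar to benzodiazepines with minimal sleep benefit."
  },
  {
    "rule_id": "BEERS-NSAID",
    "source": "BEERS2019",
    "targets": {"atc": ["M01AB", "M01AC", "M01AE", "M01AH"]},
    "rationale": "Non-COX-selective and COX-selective NSAIDs: GI bleeding, peptic ulcer, renal injury, blood-pressure elevation."
  },
  {
    "rule_id": "BEERS-FGA-ANTIHIST",
    "source": "BEERS2019",
    "targets": {"atc": ["R06AA", "R06AB"], "generic": ["hydroxyzine", "meclizine"]},
    "rationale": "First-generation antihistamines: highly anticholinergic; confusion, dry mouth, constipation, falls."
  },
  {
    "rule_id": "BEERS-TCA",
    "source": "BEERS2019",
    "targets": {"atc": ["N06AA"]},
    "rationale": "Tertiary tricyclic antidepressants: highly anticholinergic, sedating, orthostatic hypotension."
  },
  {
    "rule_id": "BEERS-DIGOXIN",
    "source": "BEERS2019",
    "targets": {"generic": ["digoxin"]},
    "rationale": "Digoxin: not first-line in atrial fibrillation or heart failure; toxicity risk with reduced renal clearance."
  },
  {
    "rule_id": "BEERS-MUSCLE-RELAX",
    "source": "BEERS2019",
    "targets": {"generic": ["cyclobenzaprine"]},
    "rationale": "Skeletal muscle relaxants: anticholinergic, sedating, questionable effectiveness at tolerated doses."
  },
  {
    "rule_id": "BEERS-ANTIPSYCH-DEMENTIA",
    "source": "BEERS2019",
    "targets": {"atc": ["N05AH"]},
    "predicates": {"ga_flag": "cognition"},
    "rationale": "Antipsychotics in cognitive impairment/dementia: increased stroke risk and mortality; avoid except for documented psychosis."
  },
  {
    "rule_id": "BEERS-ASA-PRIMARY",
    "source": "BEERS2019",
    "targets": {"generic": ["aspirin"]},
    "predicates": {"min_age": 70},
    "rationale": "Aspirin for primary prevention at age >= 70: bleeding risk likely exceeds cardiovascular benefit."
  },
  {
    "rule_id": "BEERS-OPIOID-BZD",
    "source": "BEERS2019",
    "targets": {"atc": ["N02AA", "N02AX"]},
    "predicates": {"co_medication_atc": "N05BA"},
    "rationale": "Opioid with concurrent benzodiazepine: overdose and severe respiratory depression risk."
  },
  {
    "rule_id": "BEERS-STEROID-NSAID",
    "source": "BEERS2019",
    "targets": {"atc": ["H02AB"]},
    "predicates": {"co_medication_atc": "M01A"},
    "rationale": "Systemic corticosteroid with NSAID: greatly increased peptic ulcer and GI bleeding risk."
  },
  {
    "rule_id": "STOPP-FGA-ANTIHIST",
    "source": "STOPP",
    "targets": {"atc": ["R06AA", "R06AB"], "generic": ["hydroxyzine", "meclizine"]},
    "rationale": "First-generation antihistamines: safer, less anticholinergic alternatives exist."
  },
  {
    "rule_id": "STOPP-BB-DIABETES",
    "source": "STOPP",
    "targets": {"atc": ["C07"]},
    "predicates": {"co_medication_atc": "A10"},
    "rationale": "Beta-blocker with glucose-lowering therapy: risk of masking hypoglycemic symptoms."
  },
  {
    "rule_id": "STOPP-BZD",
    "source": "STOPP",
    "targets": {"atc": ["N05BA", "N05CD", "N03AE"]},
    "rationale": "Benzodiazepines: sedation, confusion, impaired balance, falls; withdrawal syndrome if stopped abruptly."
  },
  {
    "rule_id": "STOPP-NSAID",
    "source": "STOPP",
    "targets": {"atc": ["M01AB", "M01AC", "M01AE", "M01AH"]},
    "predicates": {"ga_flag": "comorbidity"},
    "rationale": "NSAID with significant comorbidity burden (cardiovascular, renal or GI disease): adverse-event risk outweighs benefit."
  },
  {
    "rule_id": "STOPP-PPI",
    "source": "STOPP",
    "targets": {"atc": ["A02BC"]},
    "predicates": {"co_medication_atc": "A02BA"},
    "rationale": "PPI at full therapeutic dose beyond the indicated duration (proxied here by concurrent double acid suppression)."
  },
  {
    "rule_id": "STOPP-TCA-DEMENTIA",
    "source": "STOPP",
    "targets": {"atc": ["N06AA"]},
    "predicates": {"ga_flag": "cognition"},
    "rationale": "Tricyclic antidepressant with dementia: risk of worsening cognitive impairment."
  },
  {
    "rule_id": "STOPP-LOOP-DIURETIC",
    "source": "STOPP",
    "targets": {"atc": ["C03CA"]},
    "predicates": {"ga_flag": "function"},
    "rationale": "Loop diuretic in a functionally impaired patient without clear indication: urinary urgency, falls."
  },
  {
    "rule_id": "STOPP-DIGOXIN",
    "source": "STOPP",
    "targets": {"generic": ["digoxin"]},
    "rationale": "Long-term digoxin at doses risking toxicity with age-reduced renal clearance."
  },
  {
    "rule_id": "STOPP-BLADDER-ANTIMUSC-DEMENTIA",
    "source": "STOPP",
    "targets": {"atc": ["G04BD"]},
    "predicates": {"ga_flag": "cognition"},
    "rationale": "Bladder antimuscarinic with dementia or chronic cognitive impairment: risk of increased confusion and agitation."
  },
  {
    "rule_id": "STOPP-ZDRUG",
    "source": "STOPP",
    "targets": {"atc": ["N05CF"]},
    "rationale": "Z-drug hypnotics: protracted daytime sedation and ataxia in older adults."
  },
  {
    "rule_id": "STOPP-ASA-VKA",
    "source": "STOPP",
    "targets": {"generic": ["aspirin"]},
    "predicates": {"co_medication_atc": "B01AA"},
    "rationale": "Aspirin with vitamin-K antagonist without clear indication: major bleeding risk."
  },
  {
    "rule_id": "STOPP-LONG-SULFONYLUREA",
    "source": "STOPP",
    "targets": {"generic": ["glimepiride"]},
    "rationale": "Long-acting sulfonylurea: risk of prolonged hypoglycemia in older adults."
  }
]
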