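# Methods

## Problem and model

The package implements a cross-sectional medication-risk review for a
cohort of older adults (≥70) with advanced cancer starting systemic
treatment. The unit of observation is the patient; the unit of measurement
is the *regular medication occurrence* — one deduplicated generic drug a
patient reports taking, categorized as prescription, over-the-counter
(OTC), or complementary. Cancer treatments and supportive-care drugs travel
with the patient but are excluded from the regular count, from PIM
screening, and from the regular side of interaction detection, because they
are clinically governed separately.

Analyses are deliberately bivariate and descriptive: prevalences,
cross-product prevalence odds ratios (POR) with Woolf intervals, Fisher /
chi-square / t tests, one univariate logistic model (interaction odds per
additional medication), and graph summaries of the interaction structure.
No multivariable adjustment and no multiplicity correction are applied —
matching the analysis this pipeline reproduces.

## Normalization and counting

Recorded names are lowercased, dose/route/schedule tokens are stripped via
a conservative blacklist ("mg", "tablet", "er", …; unknown tokens pass
through), brand names map through a synonym table, and duplicates collapse
on (patient, generic), first occurrence kept. Different doses of one
generic are one drug. As-needed and scheduled drugs count alike. Records
whose name normalizes to empty are rejected with a warning, not an error.

Polypharmacy is ≥5 regular medications, excessive polypharmacy ≥10;
excessive patients also count as polypharmacy in prevalence tallies.
Percentages are rounded half-up to one decimal (odds ratios to two) at the
report layer only; module outputs keep full precision.

## ATC handling

Codes follow the 7-character WHO layout with level prefixes of length
1/3/4/5/7. A drug may carry several codes; one is designated primary, and
class tallies and network node assignment use the primary code only, so
each occurrence lands in exactly one subgroup and nothing is double-counted.
PIM class criteria, by contrast, match against *all* of a drug's codes,
since a criterion about a class applies to any class the substance belongs
to. Drugs absent from the formulary go to an unclassified report: retained
in medication counts, excluded from class tallies. Combination products are
not modeled; an unmapped combination lands in the unclassified report.

The shipped formulary (~150 generics) is a curated subset sufficient for
the drug classes the analyses discuss; it makes no claim of covering the
WHO index.

## PIM rules engine

Rules are data, not code: JSON objects with a source catalog (BEERS2019 or
STOPP), targets (ATC prefixes and/or generic names, union semantics), and
optional conjunctive predicates — minimum age, required covariate value,
required co-medication ATC prefix, required geriatric-assessment (GA)
impairment flag. Predicates on missing covariates fail closed (no flag) and
log the miss. The packaged ruleset (24 rules) reconstructs the
headline criterion classes (PPIs, benzodiazepines and Z-drugs, NSAIDs,
first-generation antihistamines, TCAs, digoxin, opioid+benzodiazepine,
corticosteroid+NSAID, …); it is a documented representative subset, not
either licensed catalog, so absolute PIM prevalences on synthetic cohorts
sit below the published cohort's. Class-share summaries are reported under
both denominators (per patient and per flag) because published summaries
rarely state which they use.

## Interaction detection

The knowledge base maps canonical (lexicographic) generic pairs to a
severity in {C, D, X}; duplicate entries keep the maximum severity
(X > D > C) at load. Matching is by generic name — interaction severity is
substance-specific — and the ATC hierarchy enters only when detections are
aggregated. One detection is emitted per (patient, pair): a pair occurring
in k patients contributes k occurrences to every downstream tally. DDI
enumerates all unordered pairs of distinct regular drugs; DCI enumerates
regular × cancer-treatment pairs only; supportive-care drugs are excluded
everywhere. Severities A/B of the source grading system are deliberately
unrepresentable.

## Networks

Nodes are the labels that actually interact (not the full formulary) at
medication level or an ATC rollup; edges are unordered label pairs weighted
by detection count. At rollup levels, a detection whose two drugs share a
label is reported in a self-pair tally rather than as a self-loop, and
detections involving unclassified drugs go to an unmapped tally;
edge weights + self-pairs + unmapped always sum to the input detections.

Metrics: density `2E/(N(N−1))` (0 for N<2); diameter of the largest
connected component (interaction graphs are typically disconnected at
medication level), with per-component diameters also reported; triadic
closure as global transitivity (`3·triangles / connected triples`), the
closest formalization of "the chance two nodes sharing a neighbor are
themselves connected" — mean local clustering is reported alongside as a
secondary statistic since that phrasing is ambiguous. Chord-diagram export
zeroes cells below a minimum occurrence count (defaults 20 for
all-interaction and 3 for major-interaction exports, the thresholds used in
the published figures).

## Statistics

* POR: `ad/bc`; Woolf CI `exp(ln POR ± z·SE)`, `SE = √(1/a+1/b+1/c+1/d)`,
  z = 1.959964. Any zero cell triggers the Haldane–Anscombe correction
  (+0.5 to all cells) and tags the result's method string; an empty margin
  is an error, not a number.
* Fisher's exact: two-sided by the probability-mass convention (sum of
  equally-margined tables with probability ≤ observed), delegated to scipy
  and cross-checked in tests against full hypergeometric enumeration.
* Chi-square: Pearson statistic without continuity correction,
  df = (r−1)(c−1).
* t-test: Welch by default (a pooled-variance option exists); two identical
  constant samples return p = 1 with a log message.
* Logistic per-unit OR: Newton IRLS to relative tolerance 1e-10, max 100
  iterations; Wald CI on the slope. Complete separation or non-convergence
  raises rather than returning a silent estimate.

Published-table recomputation: of the 40 published POR/CI rows transcribed
into `data/reference_tables.json`, 21 reproduce exactly (2 dp) from their
printed cells; the other 19 contain internal inconsistencies — a
transcription slip in one marital-status cell, an apparently row-shuffled
POR column in one cancer-type block, and second-decimal drifts consistent
with complete-case denominators the source does not specify. Those rows are
flagged `consistent: false` (a curation judgment made once, from the
printed numbers alone) and excluded from exact-reproduction checks.

## Synthetic cohort generator

The generator defines the study conditions the tests exercise:

* **Medication counts**: negative binomial (dispersion r = 5, mean 6.0)
  riding a log-normal frailty (σ = 0.20 on the log scale, mean-preserving),
  clamped to [0, 24]. Chosen once to match the published marginals — median
  5, range 0–24, ~61% polypharmacy, ~15–17% excessive. The published mean
  is 5.8; 6.0 is the compromise that holds the median at 5.
* **Categories**: each occurrence draws prescription/OTC/complementary at
  (0.733, 0.187, 0.080), targeting the published ~73/27 split; drugs are
  sampled without replacement within the category pool, weighted so ATC
  level-2 shares approximate the published leaders (C10 13%, C09/C07 9.5%,
  A10 7.2%, C03 6.6% within prescriptions; A11 27%, B03 14.9%, A02 14.6%,
  A12 9.8% within nonprescription). Two complementary items (turmeric,
  cranberry extract) are intentionally absent from the formulary to
  exercise the unclassified path.
* **Covariates**: drawn from the published baseline marginals (age bands,
  gender, race, education, income, marital status, cancer type, stage,
  KPS band, life expectancy); treatment line (70/30) is a plausible choice,
  unstated in the source.
* **Planted effects**: GA impairment flags are drawn conditionally on the
  patient's polypharmacy indicator at fixed odds ratios (comorbidity
  OR 3.4 from base 50.7%, function 1.64, physical 2.0, psychological 1.73 —
  each matching the published conditional prevalences), which makes the
  planted ORs exact and recoverable; a purely latent-frailty injection was
  rejected because it leaves the realized OR uncontrolled. Binary
  major-DDI/DCI outcomes are drawn from a logistic link on the medication
  count (ORs 1.39 and 1.12 per medication, intercepts anchored to ~24.7%
  and ~5.4% prevalence at the mean count) and recorded in the
  planted-truth ledger; they are separate from the mechanistic KB-based
  detections, whose true effect size a finite KB cannot pin.
* **Determinism**: one `numpy` Generator seeded from the config; identical
  seed + config gives byte-identical fixture and cohort files.

What the generator does **not** emulate: the real cohort's joint covariate
structure beyond printed marginals, dose/duration information, the size of
a licensed interaction database or criterion catalog (so absolute DDI/PIM
counts on synthetic data are smaller than published), and toxicity
outcomes. Passing tests therefore demonstrate correctness of the machinery
and recoverability of planted effects, not reproduction of the published
cohort-generated headline numbers (1854 DDIs; the 40-node, density-0.28
level-2 network), which require the raw logs.

## Problem sizes

The shared test cohort is one full-size generation (n = 718). Recovery
checks use 100–200 lightweight replicates (count + outcome sampling only)
at n = 718 and 40 full cohort generations; graph-metric oracles enumerate
exhaustively up to 15 nodes; Fisher enumeration covers totals ≤ 40. These
sizes give stable Monte-Carlo verdicts at interactive runtimes.

## Known limitations

* The rules engine supports conjunctive positive predicates only; criteria
  requiring negations ("opioid *without* laxative") or dose/duration
  conditions are out of scope.
* KB matching is exact on generic names; misspellings survive normalization
  and silently miss.
* The severity grading collapses a licensed database's richer taxonomy to
  C/D/X.
* `mean_local_clustering` and per-component diameters are informational;
  only density, diameter (largest component), and global transitivity are
  the primary metrics.
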