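"""PIM rules engine: loading, predicate evaluation, prevalence."""

import json

import pytest

from conftest import make_patient
from polyrisk.pim import PIMRule, load_ruleset, pim_prevalence, screen_patient


class TestRuleLoading:
    def test_packaged_ruleset_covers_headline_classes(self, ruleset):
        beers = [r for r in ruleset if r.source == "BEERS2019"]
        assert len(beers) >= 4
        targets = {t for r in beers for t in r.target_atc}
        assert "A02BC" in targets            # proton pump inhibitors
        assert {"N05BA", "N05CD"} <= targets  # benzodiazepines
        assert "M01AE" in targets            # NSAIDs
        assert "R06AA" in targets            # first-generation antihistamines

    def test_duplicate_rule_id_rejected(self, tmp_path):
        rule = {"rule_id": "R1", "source": "STOPP", "targets": {"generic": ["aspirin"]}}
        path = tmp_path / "rules.json"
        path.write_text(json.dumps([rule, rule]))
        with pytest.raises(ValueError, match="duplicate"):
            load_ruleset(path)

    def test_empty_file_warns(self, tmp_path, caplog):
        path = tmp_path / "rules.json"
        path.write_text("[]")
        with caplog.at_level("WARNING"):
            assert load_ruleset(path) == []
        assert "empty" in caplog.text

    def test_unknown_source_and_empty_targets_rejected(self):
        with pytest.raises(ValueError, match="unknown source"):
            PIMRule("R1", "BEERS2003", target_generic=("aspirin",))
        with pytest.raises(ValueError, match="empty target"):
            PIMRule("R1", "STOPP")

    def test_mixed_targets_match_either(self, formulary):
        rule = PIMRule("R1", "STOPP", target_atc=("A02BC",), target_generic=("warfarin",))
        by_atc = make_patient(meds=[("omeprazole", "otc")])
        by_name = make_patient(meds=[("warfarin", "prescription")])
        assert len(screen_patient(by_atc, [rule], formulary)) == 1
        assert len(screen_patient(by_name, [rule], formulary)) == 1


class TestScreening:
    def test_direct_class_match(self, formulary):
        rule = PIMRule("BEERS-PPI", "BEERS2019", target_atc=("A02BC",))
        p = make_patient(meds=[("omeprazole", "otc")])
        flags = screen_patient(p, [rule], formulary)
        assert len(flags) == 1 and flags[0].generic_name == "omeprazole"

    def test_untargeted_patient_unflagged(self, formulary, ruleset):
        p = make_patient(meds=[("metformin", "prescription")])
        assert screen_patient(p, ruleset, formulary) == []

    def test_multi_rule_fixture_patient(self, formulary, ruleset):
        # omeprazole: Beers PPI; lorazepam: Beers + STOPP benzodiazepine rules;
        # oxycodone + lorazepam: Beers opioid-with-benzo rule -> hand count
        p = make_patient(
            meds=[("omeprazole", "otc"), ("lorazepam", "prescription"),
                  ("oxycodone", "prescription")],
        )
        flags = screen_patient(p, ruleset, formulary)
        by_rule = {(f.rule_id, f.generic_name) for f in flags}
        assert ("BEERS-PPI", "omeprazole") in by_rule
        assert ("BEERS-BZD", "lorazepam") in by_rule
        assert ("STOPP-BZD", "lorazepam") in by_rule
        assert ("BEERS-OPIOID-BZD", "oxycodone") in by_rule
        assert len(flags) == 4
        sources = {f.source for f in flags}
        assert sources == {"BEERS2019", "STOPP"}

    def test_flags_sorted_deterministically(self, formulary, ruleset):
        p = make_patient(meds=[("diazepam", "prescription"), ("alprazolam", "prescription")])
        flags = screen_patient(p, ruleset, formulary)
        assert flags == sorted(flags, key=lambda f: (f.rule_id, f.generic_name))

    def test_min_age_predicate(self, formulary):
        rule = PIMRule("R1", "BEERS2019", target_generic=("aspirin",), min_age=80)
        young = make_patient(age=75, meds=[("aspirin", "otc")])
        old = make_patient(age=81, meds=[("aspirin", "otc")])
        assert screen_patient(young, [rule], formulary) == []
        assert len(screen_patient(old, [rule], formulary)) == 1

    def test_ga_flag_predicate(self, formulary):
        rule = PIMRule("R1", "STOPP", target_atc=("N06AA",), required_ga_flag="cognition")
        without = make_patient(meds=[("amitriptyline", "prescription")])
        with_flag = make_patient(meds=[("amitriptyline", "prescription")], ga=("cognition",))
        assert screen_patient(without, [rule], formulary) == []
        assert len(screen_patient(with_flag, [rule], formulary)) == 1

    def test_co_medication_predicate(self, formulary):
        rule = PIMRule(
            "R1", "STOPP", target_generic=("aspirin",), required_co_medication_atc="B01AA"
        )
        alone = make_patient(meds=[("aspirin", "otc")])
        with_vka = make_patient(meds=[("aspirin", "otc"), ("warfarin", "prescription")])
        assert screen_patient(alone, [rule], formulary) == []
        assert len(screen_patient(with_vka, [rule], formulary)) == 1

    def test_missing_covariate_fails_closed_and_logs(self, formulary, caplog):
        rule = PIMRule(
            "R1", "STOPP", target_generic=("aspirin",),
            required_covariates=(("kps", "20-60"),),
        )
        p = make_patient(meds=[("aspirin", "otc")])  # no kps covariate
        with caplog.at_level("WARNING"):
            assert screen_patient(p, [rule], formulary) == []
        assert "fails closed" in caplog.text


class TestPrevalence:
    def test_empty_cohort_rejected(self, ruleset, formulary):
        with pytest.raises(ValueError):
            pim_prevalence([], ruleset, formulary)

    def test_union_zero_when_nothing_matches(self, formulary):
        rules = [PIMRule("R1", "STOPP", target_generic=("warfarin",))]
        cohort = [make_patient(meds=[("metformin", "prescription")])]
        prev, flags = pim_prevalence(cohort, rules, formulary)
        assert prev.pct_union == 0.0 and flags == []

    def test_prevalence_matches_per_patient_reevaluation(self, synth):
        _, fixtures, cohort, _ = synth
        prev, _ = pim_prevalence(cohort, fixtures.ruleset, fixtures.formulary)
        n = len(cohort)
        flagged = {s: 0 for s in ("BEERS2019", "STOPP")}
        union = 0
        for p in cohort:
            flags = screen_patient(p, fixtures.ruleset, fixtures.formulary)
            srcs = {f.source for f in flags}
            for s in srcs:
                flagged[s] += 1
            union += bool(srcs)
        for s in flagged:
            assert prev.pct_by_source[s] == round(100 * flagged[s] / n, 1)
        assert prev.pct_union == round(100 * union / n, 1)

    def test_union_dominates_each_source(self, synth):
        _, fixtures, cohort, _ = synth
        prev, _ = pim_prevalence(cohort, fixtures.ruleset, fixtures.formulary)
        assert prev.pct_union >= max(prev.pct_by_source.values())

    def test_adding_rule_never_decreases_flags(self, synth):
        _, fixtures, cohort, _ = synth
        some = [p for p in cohort[:40]]
        base_rules = fixtures.ruleset[:5]
        extra = base_rules + [PIMRule("EXTRA", "STOPP", target_atc=("C10AA",))]
        for p in some:
            n_base = len(screen_patient(p, base_rules, fixtures.formulary))
            n_more = len(screen_patient(p, extra, fixtures.formulary))
            assert n_more >= n_base
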