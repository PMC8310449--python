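"""The five prescription checks and the aggregated review report."""

import random

import pytest

from cpmguard import (
    DosageRule,
    EntityNode,
    KnowledgeGraph,
    MedicalRecord,
    PatientProfile,
    PrescriptionItem,
    Triple,
    check_combined_use,
    check_dosage,
    check_repeated_efficacy,
    check_symptomatic,
    check_syndrome,
    gen_kg,
    gen_records,
    review_record,
)
from cpmguard.engine import CATEGORIES, EngineError
from cpmguard.fixtures import KGParams, report_alert_keys
from oracles import brute_check_alerts


@pytest.fixture()
def tiny():
    """Two conflicting drugs, one safe one, with full rule coverage."""
    g = KnowledgeGraph()
    for nid, name, etype in [
        ("dA", "drugA", "cpm_drug"),
        ("dB", "drugB", "cpm_drug"),
        ("dC", "drugC", "cpm_drug"),
        ("x", "herbX", "ingredient"),
        ("y", "herbY", "ingredient"),
        ("z", "herbZ", "ingredient"),
        ("cold", "common cold", "disease"),
        ("flu", "influenza", "disease"),
        ("cough", "cough", "symptom"),
        ("fever", "fever", "symptom"),
        ("windcold", "wind cold pattern", "syndrome"),
        ("windheat", "wind heat pattern", "syndrome"),
        ("child", "child", "population_group"),
    ]:
        g.add_entity(EntityNode(nid, name, etype))
    g.add_triple(Triple("dA", "contains_ingredient", "x"))
    g.add_triple(Triple("dB", "contains_ingredient", "y"))
    g.add_triple(Triple("dC", "contains_ingredient", "z"))
    g.add_triple(Triple("x", "incompatible_with", "y"))
    g.add_triple(Triple("dA", "indicated_for_disease", "cold"))
    g.add_triple(Triple("dB", "indicated_for_disease", "flu"))
    g.add_triple(Triple("dC", "indicated_for_disease", "cold"))
    g.add_triple(Triple("dA", "indicated_for_syndrome", "windcold"))
    g.add_triple(Triple("cold", "has_symptom", "cough"))
    g.add_triple(Triple("cold", "has_symptom", "fever"))
    g.add_dosage_rule(DosageRule("dA", "default_adult", 2, 6, "g"))
    g.add_dosage_rule(DosageRule("dA", "child", 1, 3, "g"))
    return g


def items(*refs):
    return [PrescriptionItem(r) for r in refs]


class TestCombinedUse:
    def test_single_drug_no_alert(self, tiny):
        assert check_combined_use(items("dA"), tiny) == []

    def test_planted_conflict_one_critical(self, tiny):
        alerts = check_combined_use(items("dA", "dB"), tiny)
        assert len(alerts) == 1
        a = alerts[0]
        assert a.severity == "critical" and a.drugs == ("dA", "dB")
        assert Triple("x", "incompatible_with", "y") in a.evidence

    def test_unknown_drug_downgraded_to_info(self, tiny):
        alerts = check_combined_use(items("dA", "mystery tonic"), tiny)
        assert [a.severity for a in alerts] == ["info"]

    def test_three_drugs_union_of_pairs(self, tiny):
        alerts = check_combined_use(items("dA", "dB", "dC"), tiny)
        crit = [a for a in alerts if a.severity == "critical"]
        assert {a.drugs for a in crit} == {("dA", "dB")}


class TestRepeatedEfficacy:
    def test_duplicate_is_critical(self, tiny):
        alerts = check_repeated_efficacy(items("dA", "dA"), tiny)
        assert [(a.severity, a.drugs) for a in alerts] == [("critical", ("dA",))]

    def test_shared_ingredient_is_warning(self, tiny):
        tiny.add_triple(Triple("dC", "contains_ingredient", "x"))
        alerts = check_repeated_efficacy(items("dA", "dC"), tiny, k_shared=1)
        assert [(a.severity, a.drugs, a.evidence) for a in alerts] == [
            ("warning", ("dA", "dC"), ("x",))
        ]

    def test_k_shared_threshold(self, tiny):
        tiny.add_triple(Triple("dC", "contains_ingredient", "x"))
        assert check_repeated_efficacy(items("dA", "dC"), tiny, k_shared=2) == []


class TestSymptomatic:
    def test_indicated_drug_passes(self, tiny):
        rec = MedicalRecord("r", items=items("dA"), diagnoses=["cold"])
        assert check_symptomatic(rec.items, rec, tiny) == []

    def test_off_indication_drug_warns(self, tiny):
        rec = MedicalRecord("r", items=items("dB"), diagnoses=["cold"])
        alerts = check_symptomatic(rec.items, rec, tiny)
        assert [(a.severity, a.drugs) for a in alerts] == [("warning", ("dB",))]

    def test_diagnoses_by_name_resolution(self, tiny):
        rec = MedicalRecord("r", items=items("dB"), diagnoses=["common cold"])
        assert len(check_symptomatic(rec.items, rec, tiny)) == 1

    def test_symptom_inference_path(self, tiny):
        rec = MedicalRecord("r", items=items("dB"), symptoms=["cough", "fever"])
        alerts = check_symptomatic(rec.items, rec, tiny, min_overlap=2)
        assert [(a.severity, a.drugs) for a in alerts] == [("warning", ("dB",))]

    def test_single_symptom_degrades_to_info(self, tiny):
        rec = MedicalRecord("r", items=items("dB"), symptoms=["cough"])
        alerts = check_symptomatic(rec.items, rec, tiny, min_overlap=2)
        assert [a.severity for a in alerts] == ["info"]


class TestDosage:
    def test_dose_at_max_is_inclusive(self, tiny):
        it = [PrescriptionItem("dA", single_dose=3, times_per_day=2)]
        assert check_dosage(it, PatientProfile(age_years=30), tiny) == []

    def test_overdose_for_child_cites_child_rule(self, tiny):
        it = [PrescriptionItem("dA", single_dose=3, times_per_day=2)]  # 6 g vs max 3
        alerts = check_dosage(it, PatientProfile(age_years=6), tiny)
        assert len(alerts) == 1
        (rule, observed), = alerts[0].evidence
        assert rule.population == "child" and observed == 6
        assert alerts[0].severity == "critical"

    def test_underdose_flagged(self, tiny):
        it = [PrescriptionItem("dA", single_dose=1, times_per_day=1)]
        alerts = check_dosage(it, PatientProfile(age_years=30), tiny)
        assert [a.severity for a in alerts] == ["critical"]

    def test_unit_mismatch_not_evaluated(self, tiny):
        it = [PrescriptionItem("dA", single_dose=100, times_per_day=3, unit="ml")]
        alerts = check_dosage(it, PatientProfile(age_years=30), tiny)
        assert [a.severity for a in alerts] == ["warning"]
        assert "unit mismatch" in alerts[0].message

    def test_no_rule_is_info(self, tiny):
        alerts = check_dosage(items("dB"), PatientProfile(age_years=30), tiny)
        assert [a.severity for a in alerts] == ["info"]


class TestSyndrome:
    def test_no_syndrome_single_info(self, tiny):
        rec = MedicalRecord("r", items=items("dA"))
        alerts = check_syndrome(rec.items, rec, tiny)
        assert [a.severity for a in alerts] == ["info"]

    def test_matching_syndrome_passes(self, tiny):
        rec = MedicalRecord("r", items=items("dA"), syndrome="windcold")
        assert check_syndrome(rec.items, rec, tiny) == []

    def test_mismatch_warns(self, tiny):
        rec = MedicalRecord("r", items=items("dA"), syndrome="windheat")
        alerts = check_syndrome(rec.items, rec, tiny)
        assert [(a.severity, a.drugs) for a in alerts] == [("warning", ("dA",))]

    def test_drug_without_syndrome_data_is_info(self, tiny):
        rec = MedicalRecord("r", items=items("dB"), syndrome="windcold")
        alerts = check_syndrome(rec.items, rec, tiny)
        assert [a.severity for a in alerts] == ["info"]


class TestReviewRecord:
    def test_clean_record_all_pass(self, tiny):
        rec = MedicalRecord(
            "r",
            items=[PrescriptionItem("dA", 2, 2)],
            diagnoses=["cold"],
            syndrome="windcold",
        )
        report = review_record(rec, tiny)
        assert set(report.verdicts) == set(CATEGORIES)
        assert all(v == "pass" for v in report.verdicts.values())
        assert not report.has_critical

    def test_one_violation_per_category_flags_all_five(self, tiny):
        tiny.add_triple(Triple("dC", "contains_ingredient", "x"))  # dA/dC share x
        rec = MedicalRecord(
            "r",
            items=[
                PrescriptionItem("dA", 6, 2),  # 12 g >> max 6: dosage
                PrescriptionItem("dA", 2, 1),  # duplicate: repeated
                PrescriptionItem("dB"),  # conflicts with dA; off-indication
                PrescriptionItem("dC", 1, 1),
            ],
            diagnoses=["cold"],
            syndrome="windheat",  # dA indicated only for windcold
        )
        report = review_record(rec, tiny)
        assert all(v == "flagged" for v in report.verdicts.values()), report.verdicts

    def test_record_without_items_or_text_rejected(self):
        with pytest.raises(EngineError):
            MedicalRecord("r")

    def test_report_always_contains_all_five_categories(self, demo_records):
        graph, records, _ = demo_records
        for rec in records[:10]:
            report = review_record(rec, graph)
            assert sorted(report.verdicts) == sorted(CATEGORIES)

    def test_order_invariance(self, demo_records):
        """Permuting prescription items never changes the alert multiset."""
        graph, records, _ = demo_records
        rng = random.Random(4)
        for rec in records[:15]:
            base = report_alert_keys(review_record(rec, graph))
            shuffled = list(rec.items)
            rng.shuffle(shuffled)
            permuted = MedicalRecord(
                rec.record_id,
                items=shuffled,
                diagnoses=list(reversed(rec.diagnoses)),
                symptoms=list(rec.symptoms),
                syndrome=rec.syndrome,
                patient=rec.patient,
            )
            assert report_alert_keys(review_record(permuted, graph)) == base

    def test_adding_drug_never_removes_pairwise_alerts(self, demo_records):
        """Monotonicity of combined_use / repeated_efficacy under growth."""
        graph, records, _ = demo_records
        drugs = sorted(n.id for n in graph.nodes_of_type("cpm_drug"))
        rng = random.Random(5)
        for rec in records[:15]:
            before = {
                k
                for k in report_alert_keys(review_record(rec, graph))
                if k[0] in ("combined_use", "repeated_efficacy")
            }
            extra = rng.choice(drugs)
            grown = MedicalRecord(
                rec.record_id,
                items=list(rec.items) + [PrescriptionItem(extra)],
                diagnoses=list(rec.diagnoses),
                symptoms=list(rec.symptoms),
                syndrome=rec.syndrome,
                patient=rec.patient,
            )
            after = {
                k
                for k in report_alert_keys(review_record(grown, graph))
                if k[0] in ("combined_use", "repeated_efficacy")
            }
            assert before <= after

    @pytest.mark.parametrize("seed", [21, 22])
    def test_alerts_match_brute_force_oracle(self, seed):
        """Random prescriptions on a random graph: engine output equals an
        independent re-derivation from the raw triples."""
        graph, _ = gen_kg(
            KGParams(n_drugs=12, n_ingredients=30, conflict_rate=0.03), seed=seed
        )
        drugs = sorted(n.id for n in graph.nodes_of_type("cpm_drug"))
        diseases = sorted(n.id for n in graph.nodes_of_type("disease"))
        syndromes = sorted(n.id for n in graph.nodes_of_type("syndrome"))
        rng = random.Random(seed)
        for i in range(30):
            chosen = rng.sample(drugs, rng.randint(1, 5))
            if rng.random() < 0.3:
                chosen.append(rng.choice(chosen))  # duplicates happen
            rec = MedicalRecord(
                f"r{i}",
                items=[
                    PrescriptionItem(d, round(rng.uniform(0.5, 8), 2), rng.randint(1, 3))
                    for d in chosen
                ],
                diagnoses=rng.sample(diseases, rng.randint(0, 2)),
                symptoms=[],
                syndrome=rng.choice([None] + syndromes),
                patient=PatientProfile(age_years=rng.choice([5, 30, 70])),
            )
            expected = brute_check_alerts(graph, rec)
            got = report_alert_keys(review_record(rec, graph))
            assert got == expected, rec.record_id
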