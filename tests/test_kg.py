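import random

import pytest

from cpmguard import (
    DosageRule,
    EntityNode,
    GraphError,
    GraphFormatError,
    KnowledgeGraph,
    Triple,
    gen_kg,
    load_graph,
    save_graph,
)
from cpmguard.fixtures import KGParams

from oracles import (
    brute_conflicts,
    brute_diseases_for_symptoms,
    brute_indications,
    brute_shared,
)


def small_graph():
    g = KnowledgeGraph()
    g.add_entity(EntityNode("d1", "drugA", "cpm_drug", aliases=("drug-a",)))
    g.add_entity(EntityNode("d2", "drugB", "cpm_drug"))
    g.add_entity(EntityNode("x", "herbX", "ingredient"))
    g.add_entity(EntityNode("y", "herbY", "ingredient"))
    g.add_entity(EntityNode("dis1", "fever illness", "disease"))
    g.add_entity(EntityNode("s1", "cough", "symptom"))
    return g


class TestEntities:
    def test_insert_and_lookup_by_id_name_alias(self):
        g = small_graph()
        assert g.resolve_name("d1") == "d1"
        assert g.resolve_name("drugA") == "d1"
        assert g.resolve_name("drug-a") == "d1"
        assert g.resolve_name("nothere") is None

    def test_duplicate_id_rejected(self):
        g = small_graph()
        with pytest.raises(GraphError, match="duplicate entity id"):
            g.add_entity(EntityNode("d1", "other", "cpm_drug"))

    def test_name_collision_names_both_ids(self):
        g = small_graph()
        with pytest.raises(GraphError) as exc:
            g.add_entity(EntityNode("d9", "drugA", "cpm_drug"))
        assert "d9" in str(exc.value) and "d1" in str(exc.value)

    def test_invalid_nodes_rejected(self):
        with pytest.raises(GraphError):
            EntityNode("a", "", "cpm_drug")
        with pytest.raises(GraphError):
            EntityNode("a", "n", "not_a_type")
        with pytest.raises(GraphError):
            EntityNode("a", "n", "cpm_drug", aliases=("n",))
        with pytest.raises(GraphError):
            EntityNode("a", "n", "cpm_drug", aliases=("z", "z"))

    def test_alias_lookup_over_many_random_nodes(self):
        rng = random.Random(0)
        g = KnowledgeGraph()
        expected = {}
        for i in range(100):
            nid = f"n{i}"
            aliases = tuple(f"alias{i}_{j}" for j in range(rng.randint(0, 3)))
            g.add_entity(EntityNode(nid, f"name{i}", "ingredient", aliases=aliases))
            expected[f"name{i}"] = nid
            for a in aliases:
                expected[a] = nid
        for label, nid in expected.items():
            assert g.resolve_name(label) == nid


class TestTriples:
    def test_valid_triple_stored(self):
        g = small_graph()
        g.add_triple(Triple("d1", "contains_ingredient", "x"))
        assert Triple("d1", "contains_ingredient", "x") in g.triples

    def test_signature_violation_names_etypes(self):
        g = small_graph()
        with pytest.raises(GraphError, match="disease.*cpm_drug|cpm_drug.*disease"):
            g.add_triple(Triple("dis1", "has_symptom", "d1"))

    def test_unknown_endpoint(self):
        g = small_graph()
        with pytest.raises(GraphError, match="ghost"):
            g.add_triple(Triple("d1", "contains_ingredient", "ghost"))

    def test_self_loop_rejected(self):
        g = small_graph()
        for rel in ("incompatible_with", "fears"):
            with pytest.raises(GraphError, match="self-loop"):
                g.add_triple(Triple("x", rel, "x"))

    def test_duplicate_triples_idempotent(self):
        g = small_graph()
        g.add_triple(Triple("x", "incompatible_with", "y"))
        g.add_triple(Triple("y", "incompatible_with", "x"))  # same unordered pair
        assert sum(1 for t in g.triples if t.relation == "incompatible_with") == 1


class TestQueries:
    def test_planted_conflict_found(self):
        g = small_graph()
        g.add_triple(Triple("d1", "contains_ingredient", "x"))
        g.add_triple(Triple("d2", "contains_ingredient", "y"))
        g.add_triple(Triple("x", "incompatible_with", "y"))
        assert g.ingredient_conflicts("d1", "d2") == [("x", "y", "incompatible_with")]

    def test_conflict_free_pair_empty(self):
        g = small_graph()
        g.add_triple(Triple("d1", "contains_ingredient", "x"))
        g.add_triple(Triple("d2", "contains_ingredient", "y"))
        assert g.ingredient_conflicts("d1", "d2") == []

    def test_unknown_drug_raises(self):
        g = small_graph()
        with pytest.raises(GraphError):
            g.ingredient_conflicts("d1", "nope")
        with pytest.raises(GraphError):
            g.shared_ingredients("nope", "d1")
        with pytest.raises(GraphError):
            g.indications("x")  # an ingredient, not a drug

    def test_shared_with_self_is_full_ingredient_set(self):
        g = small_graph()
        g.add_triple(Triple("d1", "contains_ingredient", "x"))
        g.add_triple(Triple("d1", "contains_ingredient", "y"))
        assert g.shared_ingredients("d1", "d1") == {"x", "y"}

    def test_indications_empty_without_edges(self):
        g = small_graph()
        assert g.indications("d1") == (set(), set())

    def test_diseases_for_symptoms_ranking(self):
        g = small_graph()
        g.add_entity(EntityNode("s2", "ache", "symptom"))
        g.add_entity(EntityNode("s3", "chill", "symptom"))
        for s in ("s1", "s2", "s3"):
            g.add_triple(Triple("dis1", "has_symptom", s))
        assert g.diseases_for_symptoms(["s1", "s2"], min_overlap=2) == [("dis1", 2)]
        assert g.diseases_for_symptoms([], min_overlap=1) == []

    def test_unknown_symptom_skipped_with_warning(self, caplog):
        g = small_graph()
        g.add_triple(Triple("dis1", "has_symptom", "s1"))
        with caplog.at_level("WARNING", logger="cpmguard.kg"):
            out = g.diseases_for_symptoms(["s1", "bogus"], min_overlap=1)
        assert out == [("dis1", 1)]
        assert any("bogus" in rec.message for rec in caplog.records)

    @pytest.mark.parametrize("graph_seed", [7, 8, 9])
    def test_oracle_equivalence_random_graphs(self, graph_seed):
        """Indexed queries agree exactly with brute-force triple scans."""
        g, _ = gen_kg(KGParams(n_drugs=15, n_ingredients=40, conflict_rate=0.02), seed=graph_seed)
        drugs = sorted(n.id for n in g.nodes_of_type("cpm_drug"))
        symptoms = sorted(n.id for n in g.nodes_of_type("symptom"))
        rng = random.Random(graph_seed)
        for i, a in enumerate(drugs):
            for b in drugs[i:]:
                assert g.ingredient_conflicts(a, b) == brute_conflicts(g, a, b)
                assert g.shared_ingredients(a, b) == brute_shared(g, a, b)
            assert g.indications(a) == brute_indications(g, a)
        for _ in range(20):
            query = rng.sample(symptoms, rng.randint(1, 6))
            k = rng.randint(1, 3)
            assert g.diseases_for_symptoms(query, k) == brute_diseases_for_symptoms(g, query, k)

    def test_conflict_symmetry(self):
        g, _ = gen_kg(KGParams(n_drugs=12, n_ingredients=30, conflict_rate=0.05), seed=5)
        drugs = sorted(n.id for n in g.nodes_of_type("cpm_drug"))
        for i, a in enumerate(drugs):
            for b in drugs[i + 1 :]:
                ab = {frozenset((x, y)) for x, y, _ in g.ingredient_conflicts(a, b)}
                ba = {frozenset((x, y)) for x, y, _ in g.ingredient_conflicts(b, a)}
                assert ab == ba


class TestDosageRules:
    def graph_with_rules(self):
        g = small_graph()
        g.add_entity(EntityNode("child", "child", "population_group"))
        g.add_entity(EntityNode("pregnant", "pregnant", "population_group"))
        g.add_dosage_rule(DosageRule("d1", "default_adult", 1, 6, "g"))
        g.add_dosage_rule(DosageRule("d1", "child", 0.5, 3, "g"))
        g.add_dosage_rule(DosageRule("d1", "pregnant", 0.5, 2, "g"))
        return g

    def test_fallback_to_default(self):
        g = self.graph_with_rules()
        rule = g.dosage_rule_lookup("d1", {"elderly_unknown"})
        assert rule.population == "default_adult"

    def test_specific_rule_wins(self):
        g = self.graph_with_rules()
        assert g.dosage_rule_lookup("d1", {"child"}).population == "child"

    def test_priority_order_pregnant_over_child(self):
        g = self.graph_with_rules()
        assert g.dosage_rule_lookup("d1", {"child", "pregnant"}).population == "pregnant"

    def test_no_rules_returns_none(self):
        g = self.graph_with_rules()
        assert g.dosage_rule_lookup("d2", {"child"}) is None

    def test_duplicate_rule_rejected(self):
        g = self.graph_with_rules()
        with pytest.raises(GraphError, match="duplicate dosage rule"):
            g.add_dosage_rule(DosageRule("d1", "child", 1, 2, "g"))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(GraphError):
            DosageRule("d1", "default_adult", 3, 1, "g")
        with pytest.raises(GraphError):
            DosageRule("d1", "default_adult", 0, 1, "g")


class TestSerialization:
    def test_round_trip_identity(self, tmp_path, demo_graph):
        graph, _ = demo_graph
        p = tmp_path / "g.jsonl"
        save_graph(graph, p)
        assert load_graph(p) == graph

    def test_round_trip_byte_stable(self, tmp_path, demo_graph):
        graph, _ = demo_graph
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        save_graph(graph, p1)
        save_graph(load_graph(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_counts_match_manifest(self, tmp_path, demo_graph):
        graph, manifest = demo_graph
        p = tmp_path / "g.jsonl"
        save_graph(graph, p)
        assert load_graph(p).stats() == manifest.counts

    def test_dangling_endpoint_names_line(self, tmp_path):
        g = small_graph()
        g.add_triple(Triple("d1", "contains_ingredient", "x"))
        p = tmp_path / "g.jsonl"
        save_graph(g, p)
        lines = p.read_text().splitlines()
        bad = lines + ['{"kind": "triple", "head": "d1", "relation": "contains_ingredient", "tail": "ghost"}']
        p.write_text("\n".join(bad) + "\n")
        with pytest.raises(GraphFormatError) as exc:
            load_graph(p)
        assert f"line {len(bad)}" in str(exc.value)

    def test_any_single_corruption_detected(self, tmp_path):
        """Corrupting any one record of a valid file fails validation."""
        g, _ = gen_kg(KGParams(n_drugs=5, n_ingredients=12, n_diseases=4, n_symptoms=8), seed=42)
        p = tmp_path / "g.jsonl"
        save_graph(g, p)
        lines = p.read_text().splitlines()
        corruptions = [
            '{"kind": "entity", "id": "zz", "name": "dup", "etype": "no_such_type", "aliases": []}',
            '{"kind": "triple", "head": "missing", "relation": "fears", "tail": "alsomissing"}',
            "not json at all",
            '{"no_kind": true}',
        ]
        for i in range(len(lines)):
            for corrupt in corruptions[: 2 if i % 3 else 4]:
                mutated = list(lines)
                mutated[i] = corrupt
                (tmp_path / "bad.jsonl").write_text("\n".join(mutated) + "\n")
                with pytest.raises(GraphFormatError):
                    load_graph(tmp_path / "bad.jsonl")
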