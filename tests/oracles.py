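"""Brute-force reference implementations used only by the tests.

All oracles work from the raw triple set / record fields, independently of
the indexed query paths and check implementations they are compared with.
"""


def brute_ingredients(graph, drug):
    return {
        t.tail
        for t in graph.triples
        if t.head == drug and t.relation == "contains_ingredient"
    }


def brute_conflicts(graph, drug_a, drug_b):
    trips = {(t.head, t.relation, t.tail) for t in graph.triples}
    out = []
    for a in brute_ingredients(graph, drug_a):
        for b in brute_ingredients(graph, drug_b):
            if a == b:
                continue
            for rel in ("incompatible_with", "fears"):
                if (a, rel, b) in trips or (b, rel, a) in trips:
                    out.append((a, b, rel))
    return sorted(out)


def brute_shared(graph, drug_a, drug_b):
    return brute_ingredients(graph, drug_a) & brute_ingredients(graph, drug_b)


def brute_indications(graph, drug):
    return (
        {
            t.tail
            for t in graph.triples
            if t.head == drug and t.relation == "indicated_for_disease"
        },
        {
            t.tail
            for t in graph.triples
            if t.head == drug and t.relation == "indicated_for_syndrome"
        },
    )


def brute_diseases_for_symptoms(graph, symptom_ids, min_overlap):
    known = {
        s for s in symptom_ids if s in graph.nodes and graph.nodes[s].etype == "symptom"
    }
    counts = {}
    for t in graph.triples:
        if t.relation == "has_symptom" and t.tail in known:
            counts[t.head] = counts.get(t.head, 0) + 1
    ranked = [(d, c) for d, c in counts.items() if c >= min_overlap]
    ranked.sort(key=lambda dc: (-dc[1], dc[0]))
    return ranked


# ----------------------------------------------------- rule-check oracles


def brute_check_alerts(graph, record, k_shared=1, min_overlap=2):
    """Expected warning/critical alert keys for a structured record whose
    item drug_refs are entity ids: set of (category, severity, drug tuple)."""
    keys = set()
    drug_ids = [
        i.drug_ref
        for i in record.items
        if i.drug_ref in graph.nodes and graph.nodes[i.drug_ref].etype == "cpm_drug"
    ]
    distinct = sorted(set(drug_ids))
    for i, a in enumerate(distinct):
        for b in distinct[i + 1 :]:
            if brute_conflicts(graph, a, b):
                keys.add(("combined_use", "critical", (a, b)))
            if len(brute_shared(graph, a, b)) >= k_shared:
                keys.add(("repeated_efficacy", "warning", (a, b)))
    for d in distinct:
        if drug_ids.count(d) > 1:
            keys.add(("repeated_efficacy", "critical", (d,)))
    diagnoses = {
        graph.resolve_name(x)
        for x in record.diagnoses
        if graph.resolve_name(x) is not None
    }
    if not diagnoses:
        sym_ids = [graph.resolve_name(s) or s for s in record.symptoms]
        diagnoses = {d for d, _ in brute_diseases_for_symptoms(graph, sym_ids, min_overlap)}
    if diagnoses:
        for d in distinct:
            ind, _ = brute_indications(graph, d)
            if ind and not (ind & diagnoses):
                keys.add(("symptomatic", "warning", (d,)))
    groups = record.patient.population_group_ids(graph)
    priority = (
        "pregnant", "lactating", "child", "elderly",
        "hepatic_impairment", "renal_impairment",
    )

    def lookup(d):
        cands = [
            r
            for (drug, pop), r in graph.dosage_rules.items()
            if drug == d and pop in groups
        ]
        if cands:
            def rank(r):
                name = graph.nodes[r.population].name
                return (
                    priority.index(name) if name in priority else len(priority),
                    r.population,
                )
            return min(cands, key=rank)
        return graph.dosage_rules.get((d, "default_adult"))

    for item in record.items:
        d = item.drug_ref
        if d not in set(distinct):
            continue
        rule = lookup(d)
        if rule is None:
            continue
        if item.unit != rule.unit:
            keys.add(("dosage", "warning", (d,)))
        elif not (rule.min_daily <= item.daily_dose <= rule.max_daily):
            keys.add(("dosage", "critical", (d,)))
    if record.syndrome:
        syn = graph.resolve_name(record.syndrome)
        for d in distinct:
            _, syns = brute_indications(graph, d)
            if syns and syn not in syns:
                keys.add(("syndrome", "warning", (d,)))
    return keys
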