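"""Typed knowledge graph serving as the rule base for prescription monitoring.

The graph holds six kinds of entities — Chinese patent medicines (CPM,
finished multi-ingredient products), their herbal ingredients, diseases,
symptoms, TCM syndromes, and special population groups — connected by a
closed set of relations.  Two relations encode the classical pairwise
herb taboos: ``incompatible_with`` (the "eighteen contraindications",
symmetric) and ``fears`` (the "nineteen fears", traditionally directed
"A fears B").  Product-level conflict between two CPM is defined as the
existence of any cross-product ingredient pair carrying either relation.

Dosage limits are attached per (drug, population group) with a
``default_adult`` fallback, so that dose checking can be specialised for
children, the elderly, pregnancy, etc.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

ENTITY_TYPES = frozenset(
    {"cpm_drug", "ingredient", "disease", "symptom", "syndrome", "population_group"}
)

#: relation -> (allowed head etypes, allowed tail etypes)
RELATION_SIGNATURES: dict[str, tuple[frozenset[str], frozenset[str]]] = {
    "contains_ingredient": (frozenset({"cpm_drug"}), frozenset({"ingredient"})),
    "incompatible_with": (frozenset({"ingredient"}), frozenset({"ingredient"})),
    "fears": (frozenset({"ingredient"}), frozenset({"ingredient"})),
    "indicated_for_disease": (frozenset({"cpm_drug"}), frozenset({"disease"})),
    "indicated_for_syndrome": (frozenset({"cpm_drug"}), frozenset({"syndrome"})),
    "contraindicated_for_population": (
        frozenset({"cpm_drug"}),
        frozenset({"population_group"}),
    ),
    "has_symptom": (frozenset({"disease"}), frozenset({"symptom"})),
    "contributing_factor": (frozenset({"disease"}), frozenset({"symptom", "disease"})),
}

RELATIONS = frozenset(RELATION_SIGNATURES)

#: Tie-break order when several population-specific dosage rules apply.
#: More vulnerable groups win; matching is by the canonical *name* of the
#: population_group node so graphs may choose their own ids.
POPULATION_PRIORITY = (
    "pregnant",
    "lactating",
    "child",
    "elderly",
    "hepatic_impairment",
    "renal_impairment",
)

DEFAULT_POPULATION = "default_adult"


class GraphError(ValueError):
    """Any violation of the graph schema or its invariants."""


class GraphFormatError(GraphError):
    """Raised by :func:`load_graph`; carries per-line error messages."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass(frozen=True)
class EntityNode:
    id: str
    name: str
    etype: str
    aliases: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.id:
            raise GraphError("entity id must be non-empty")
        if not self.name:
            raise GraphError(f"entity {self.id!r}: name must be non-empty")
        if self.etype not in ENTITY_TYPES:
            raise GraphError(
                f"entity {self.id!r}: unknown etype {self.etype!r} "
                f"(expected one of {sorted(ENTITY_TYPES)})"
            )
        aliases = tuple(self.aliases)
        object.__setattr__(self, "aliases", aliases)
        if len(set(aliases)) != len(aliases):
            raise GraphError(f"entity {self.id!r}: duplicate aliases")
        if self.name in aliases:
            raise GraphError(f"entity {self.id!r}: alias equals canonical name")


@dataclass(frozen=True)
class Triple:
    head: str
    relation: str
    tail: str

    def __post_init__(self):
        if self.relation not in RELATIONS:
            raise GraphError(f"unknown relation {self.relation!r}")


@dataclass(frozen=True)
class DosageRule:
    drug: str
    population: str  # population_group id or "default_adult"
    min_daily: float
    max_daily: float
    unit: str

    def __post_init__(self):
        if not (0 < self.min_daily <= self.max_daily):
            raise GraphError(
                f"dosage rule for {self.drug!r}/{self.population!r}: "
                f"need 0 < min_daily <= max_daily, got "
                f"({self.min_daily}, {self.max_daily})"
            )


class KnowledgeGraph:
    """Entity nodes + relation triples + dosage rules, with name/alias index.

    ``incompatible_with`` is stored once per unordered pair but every query
    treats it symmetrically; ``fears`` keeps its traditional direction in
    storage and evidence but conflict queries ignore the direction.
    """

    def __init__(self):
        self.nodes: dict[str, EntityNode] = {}
        self._name_index: dict[str, str] = {}  # name or alias -> id
        self._nx = nx.MultiDiGraph()
        self._triples: set[Triple] = set()
        self.dosage_rules: dict[tuple[str, str], DosageRule] = {}

    # ------------------------------------------------------------------ nodes

    def add_entity(self, node: EntityNode) -> None:
        if node.id in self.nodes:
            raise GraphError(f"duplicate entity id {node.id!r}")
        for label in (node.name, *node.aliases):
            other = self._name_index.get(label)
            if other is not None and other != node.id:
                raise GraphError(
                    f"name/alias {label!r} of entity {node.id!r} already maps "
                    f"to entity {other!r}"
                )
        self.nodes[node.id] = node
        self._nx.add_node(node.id)
        for label in (node.name, *node.aliases):
            self._name_index[label] = node.id

    def resolve_name(self, label: str) -> str | None:
        """Return the entity id for a canonical name, alias, or id itself."""
        if label in self.nodes:
            return label
        return self._name_index.get(label)

    def node_by_name(self, label: str) -> EntityNode | None:
        nid = self.resolve_name(label)
        return self.nodes[nid] if nid is not None else None

    def nodes_of_type(self, etype: str) -> list[EntityNode]:
        return [n for n in self.nodes.values() if n.etype == etype]

    # ---------------------------------------------------------------- triples

    def _check_endpoint(self, eid: str, role: str, triple: Triple) -> EntityNode:
        node = self.nodes.get(eid)
        if node is None:
            raise GraphError(f"{role} {eid!r} of triple {triple} not in graph")
        return node

    def add_triple(self, triple: Triple) -> None:
        head = self._check_endpoint(triple.head, "head", triple)
        tail = self._check_endpoint(triple.tail, "tail", triple)
        heads, tails = RELATION_SIGNATURES[triple.relation]
        if head.etype not in heads or tail.etype not in tails:
            raise GraphError(
                f"relation {triple.relation!r} does not accept "
                f"{head.etype!r} -> {tail.etype!r} (triple {triple.head!r} -> "
                f"{triple.tail!r})"
            )
        if triple.relation in ("incompatible_with", "fears") and triple.head == triple.tail:
            raise GraphError(f"self-loop {triple.relation!r} on {triple.head!r}")
        if triple.relation == "incompatible_with":
            # stored once per unordered pair
            a, b = sorted((triple.head, triple.tail))
            triple = Triple(a, "incompatible_with", b)
        if triple in self._triples:
            return  # idempotent
        self._triples.add(triple)
        self._nx.add_edge(triple.head, triple.tail, key=triple.relation)

    @property
    def triples(self) -> set[Triple]:
        return set(self._triples)

    def _out(self, eid: str, relation: str) -> set[str]:
        if eid not in self._nx:
            return set()
        return {
            v
            for _, v, k in self._nx.out_edges(eid, keys=True)
            if k == relation
        }

    def _in(self, eid: str, relation: str) -> set[str]:
        if eid not in self._nx:
            return set()
        return {
            u
            for u, _, k in self._nx.in_edges(eid, keys=True)
            if k == relation
        }

    # ----------------------------------------------------------- dosage rules

    def add_dosage_rule(self, rule: DosageRule) -> None:
        if rule.drug not in self.nodes or self.nodes[rule.drug].etype != "cpm_drug":
            raise GraphError(f"dosage rule references unknown cpm_drug {rule.drug!r}")
        if rule.population != DEFAULT_POPULATION:
            pop = self.nodes.get(rule.population)
            if pop is None or pop.etype != "population_group":
                raise GraphError(
                    f"dosage rule for {rule.drug!r} references unknown "
                    f"population_group {rule.population!r}"
                )
        key = (rule.drug, rule.population)
        if key in self.dosage_rules:
            raise GraphError(
                f"duplicate dosage rule for drug {rule.drug!r}, "
                f"population {rule.population!r}"
            )
        self.dosage_rules[key] = rule

    # ---------------------------------------------------------------- queries

    def _require_drug(self, drug: str) -> None:
        node = self.nodes.get(drug)
        if node is None or node.etype != "cpm_drug":
            raise GraphError(f"unknown cpm_drug id {drug!r}")

    def ingredients(self, drug: str) -> set[str]:
        self._require_drug(drug)
        return self._out(drug, "contains_ingredient")

    def ingredient_conflicts(
        self, drug_a: str, drug_b: str
    ) -> list[tuple[str, str, str]]:
        """All taboo ingredient pairs between two products.

        Returns ``(ingredient_of_a, ingredient_of_b, relation)`` for every
        cross-product pair joined by ``incompatible_with`` or ``fears`` in
        either direction.  Symmetric in the two drugs up to swapping the
        pair order; exhaustive over the cross product.
        """
        ing_a = self.ingredients(drug_a)
        ing_b = self.ingredients(drug_b)
        out = []
        for a in ing_a:
            for b in ing_b:
                if a == b:
                    continue
                for rel in ("incompatible_with", "fears"):
                    if (
                        Triple(a, rel, b) in self._triples
                        or Triple(b, rel, a) in self._triples
                    ):
                        out.append((a, b, rel))
        out.sort()
        return out

    def conflict_evidence(
        self, drug_a: str, drug_b: str
    ) -> list[Triple]:
        """The stored triples behind :meth:`ingredient_conflicts`.

        ``fears`` evidence keeps its stored direction even when the query
        matched it in reverse.
        """
        evidence = []
        for a, b, rel in self.ingredient_conflicts(drug_a, drug_b):
            if Triple(a, rel, b) in self._triples:
                evidence.append(Triple(a, rel, b))
            else:
                evidence.append(Triple(b, rel, a))
        # dedupe, stable order
        seen: set[Triple] = set()
        out = []
        for t in evidence:
            if t not in seen:
                seen.add(t)
                out.append(t)
        return out

    def shared_ingredients(self, drug_a: str, drug_b: str) -> set[str]:
        return self.ingredients(drug_a) & self.ingredients(drug_b)

    def indications(self, drug: str) -> tuple[set[str], set[str]]:
        self._require_drug(drug)
        return (
            self._out(drug, "indicated_for_disease"),
            self._out(drug, "indicated_for_syndrome"),
        )

    def disease_symptoms(self, disease: str) -> set[str]:
        return self._out(disease, "has_symptom")

    def diseases_for_symptoms(
        self, symptom_ids, min_overlap: int = 1
    ) -> list[tuple[str, int]]:
        """Rank diseases by how many of the given symptoms they explain.

        Unknown symptom ids are skipped with a logged warning so that
        unlinkable NER output degrades gracefully instead of aborting the
        review.
        """
        if min_overlap < 1:
            raise GraphError("min_overlap must be >= 1")
        known: set[str] = set()
        for sid in symptom_ids:
            node = self.nodes.get(sid)
            if node is None or node.etype != "symptom":
                logger.warning("unknown symptom id %r skipped", sid)
                continue
            known.add(sid)
        counts: dict[str, int] = {}
        for sid in known:
            for disease in self._in(sid, "has_symptom"):
                counts[disease] = counts.get(disease, 0) + 1
        ranked = [(d, c) for d, c in counts.items() if c >= min_overlap]
        ranked.sort(key=lambda dc: (-dc[1], dc[0]))
        return ranked

    def dosage_rule_lookup(
        self, drug: str, population_groups
    ) -> DosageRule | None:
        """Most specific applicable dosage rule, else the adult default.

        ``population_groups`` is a set of population_group ids that apply to
        the patient.  When several group-specific rules apply the fixed
        priority order (pregnant > lactating > child > elderly > hepatic >
        renal) on the group's canonical name breaks the tie.
        """
        self._require_drug(drug)
        groups = set(population_groups)

        def priority(pop_id: str) -> tuple[int, str]:
            node = self.nodes.get(pop_id)
            name = node.name if node else pop_id
            try:
                return (POPULATION_PRIORITY.index(name), pop_id)
            except ValueError:
                return (len(POPULATION_PRIORITY), pop_id)

        applicable = [
            rule
            for (d, pop), rule in self.dosage_rules.items()
            if d == drug and pop in groups
        ]
        if applicable:
            return min(applicable, key=lambda r: priority(r.population))
        return self.dosage_rules.get((drug, DEFAULT_POPULATION))

    # ------------------------------------------------------------------ stats

    def stats(self) -> dict:
        by_etype: dict[str, int] = {}
        for n in self.nodes.values():
            by_etype[n.etype] = by_etype.get(n.etype, 0) + 1
        by_rel: dict[str, int] = {}
        for t in self._triples:
            by_rel[t.relation] = by_rel.get(t.relation, 0) + 1
        return {
            "n_nodes": len(self.nodes),
            "n_triples": len(self._triples),
            "n_dosage_rules": len(self.dosage_rules),
            "nodes_by_etype": dict(sorted(by_etype.items())),
            "triples_by_relation": dict(sorted(by_rel.items())),
        }

    def __eq__(self, other) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self._triples == other._triples
            and self.dosage_rules == other.dosage_rules
        )


# ------------------------------------------------------------- serialization


def save_graph(graph: KnowledgeGraph, path) -> None:
    """Write the graph as JSON Lines: entity / triple / dosage_rule records."""
    with open(path, "w", encoding="utf-8") as fh:
        for nid in sorted(graph.nodes):
            n = graph.nodes[nid]
            fh.write(
                json.dumps(
                    {
                        "kind": "entity",
                        "id": n.id,
                        "name": n.name,
                        "etype": n.etype,
                        "aliases": list(n.aliases),
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
        for t in sorted(graph.triples, key=lambda t: (t.relation, t.head, t.tail)):
            fh.write(
                json.dumps(
                    {"kind": "triple", "head": t.head, "relation": t.relation, "tail": t.tail},
                    ensure_ascii=False,
                )
                + "\n"
            )
        for key in sorted(graph.dosage_rules):
            r = graph.dosage_rules[key]
            fh.write(
                json.dumps(
                    {
                        "kind": "dosage_rule",
                        "drug": r.drug,
                        "population": r.population,
                        "min_daily": r.min_daily,
                        "max_daily": r.max_daily,
                        "unit": r.unit,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def export_triples_tsv(graph: KnowledgeGraph, path) -> None:
    """Plain (head, relation, tail) TSV for eyeballing the rule base."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("head\trelation\ttail\n")
        for t in sorted(graph.triples, key=lambda t: (t.relation, t.head, t.tail)):
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")


def load_graph(path) -> KnowledgeGraph:
    """Load and validate a JSON Lines graph file.

    Every record is validated; all failures are collected and reported with
    their 1-based line numbers in a single :class:`GraphFormatError`.
    Records may appear in any order (entities are applied first).
    """
    entities: list[tuple[int, dict]] = []
    others: list[tuple[int, dict]] = []
    errors: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                errors.append(f"line {lineno}: invalid JSON ({exc.msg})")
                continue
            if not isinstance(rec, dict) or "kind" not in rec:
                errors.append(f"line {lineno}: record must be an object with a 'kind'")
                continue
            if rec["kind"] == "entity":
                entities.append((lineno, rec))
            elif rec["kind"] in ("triple", "dosage_rule"):
                others.append((lineno, rec))
            else:
                errors.append(f"line {lineno}: unknown record kind {rec['kind']!r}")

    graph = KnowledgeGraph()
    for lineno, rec in entities:
        try:
            node = EntityNode(
                id=rec["id"],
                name=rec["name"],
                etype=rec["etype"],
                aliases=tuple(rec.get("aliases", ())),
            )
            graph.add_entity(node)
        except (GraphError, KeyError, TypeError) as exc:
            errors.append(f"line {lineno}: {exc}")
    for lineno, rec in others:
        try:
            if rec["kind"] == "triple":
                graph.add_triple(Triple(rec["head"], rec["relation"], rec["tail"]))
            else:
                graph.add_dosage_rule(
                    DosageRule(
                        drug=rec["drug"],
                        population=rec["population"],
                        min_daily=float(rec["min_daily"]),
                        max_daily=float(rec["max_daily"]),
                        unit=rec["unit"],
                    )
                )
        except (GraphError, KeyError, TypeError, ValueError) as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise GraphFormatError(errors)
    return graph
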