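"""Deterministic synthetic fixtures with planted, bookkept violations.

Real pharmacopoeia content, guideline corpora, and hospital records are
proprietary; every other module is therefore exercised on synthetic stand-ins
generated here:

* :func:`gen_kg` — a random but schema-valid knowledge graph (drugs with
  ingredient sets, taboo ingredient pairs, disease-symptom bipartite edges,
  indications, syndromes, dosage rules);
* :func:`gen_bio_corpus` — BIO-tagged sentences in a whitespace
  pseudo-language embedding graph entity names, with gold mentions;
* :func:`gen_records` — medical records in which each violation category is
  planted with a requested probability and logged as gold truth.

Planted violations are constructed so as not to interfere with one another
(a drug added for a taboo-pair violation is verified not to also share
ingredients with the rest of the prescription, and so on); the gold alert
list of a record is therefore exactly the warning/critical alert set the
rule engine should produce, which is what the end-to-end recovery tests
assert.  Identical (params, seed) reproduce byte-identical files.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field

from .engine import MedicalRecord, PatientProfile, PrescriptionItem
from .kg import DEFAULT_POPULATION, POPULATION_PRIORITY, DosageRule, EntityNode, KnowledgeGraph, Triple
from .ner import BIOSequence, EntityMention, Lexicon, bio_encode, build_lexicon

CATEGORIES = ("combined_use", "repeated_efficacy", "symptomatic", "dosage", "syndrome")

FILLER_TOKENS = (
    "patient", "reports", "of", "and", "with", "was", "given", "daily",
    "after", "admission", "improved", "on", "exam", "noted", "stable",
    "course", "treatment", "discharged", "the", "follow",
)


class FixtureError(ValueError):
    pass


@dataclass
class KGParams:
    """Size and density knobs of the synthetic rule base.

    Defaults give a desk-scale graph dense enough that every violation
    category has candidate drugs, yet sparse enough that conflict-free
    prescriptions of up to five products exist.
    """

    n_drugs: int = 30
    n_ingredients: int = 90
    n_diseases: int = 20
    n_symptoms: int = 60
    n_syndromes: int = 8
    min_ingredients_per_drug: int = 2
    max_ingredients_per_drug: int = 8
    conflict_rate: float = 0.005  # per unordered ingredient pair
    min_symptoms_per_disease: int = 3
    max_symptoms_per_disease: int = 12

    def validate(self) -> None:
        if min(self.n_drugs, self.n_ingredients, self.n_diseases, self.n_symptoms, self.n_syndromes) < 1:
            raise FixtureError("all size parameters must be positive")
        if not (0 <= self.conflict_rate <= 1):
            raise FixtureError("conflict_rate must be in [0, 1]")
        if self.min_ingredients_per_drug > self.n_ingredients:
            raise FixtureError(
                f"cannot draw {self.min_ingredients_per_drug} ingredients per drug "
                f"from only {self.n_ingredients}"
            )
        if self.min_symptoms_per_disease > self.n_symptoms:
            raise FixtureError(
                f"cannot draw {self.min_symptoms_per_disease} symptoms per disease "
                f"from only {self.n_symptoms}"
            )


@dataclass
class FixtureManifest:
    seed: int
    params: dict
    counts: dict = field(default_factory=dict)
    conflict_ingredient_pairs: list = field(default_factory=list)
    drug_conflict_pairs: list = field(default_factory=list)
    drug_shared_pairs: list = field(default_factory=list)
    gold_alerts: dict = field(default_factory=dict)  # record_id -> [alert dicts]
    gold_mentions: dict = field(default_factory=dict)  # record_id -> [mention dicts]

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, ensure_ascii=False, sort_keys=True, indent=1)

    @classmethod
    def load(cls, path) -> "FixtureManifest":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


# ------------------------------------------------------------------ gen_kg


def gen_kg(params: KGParams | None = None, seed: int = 0) -> tuple[KnowledgeGraph, FixtureManifest]:
    """Generate a schema-valid random knowledge graph plus its manifest."""
    p = params or KGParams()
    p.validate()
    rng = random.Random(seed)
    g = KnowledgeGraph()

    for name in POPULATION_PRIORITY:
        g.add_entity(EntityNode(id=name, name=name, etype="population_group"))

    ingredients = [f"ing{i:03d}" for i in range(p.n_ingredients)]
    for i, iid in enumerate(ingredients):
        aliases = (f"ingword{i:03d}_alt",) if rng.random() < 0.2 else ()
        g.add_entity(EntityNode(id=iid, name=f"ingword{i:03d}", etype="ingredient", aliases=aliases))

    drugs = [f"drug{i:02d}" for i in range(p.n_drugs)]
    for i, did in enumerate(drugs):
        # some product names are two-token phrases, as real brand names are
        name = f"drugword{i:02d}" + (" granule" if rng.random() < 0.3 else "")
        aliases = (f"drugword{i:02d}_alt",) if rng.random() < 0.3 else ()
        g.add_entity(EntityNode(id=did, name=name, etype="cpm_drug", aliases=aliases))

    diseases = [f"dis{i:02d}" for i in range(p.n_diseases)]
    for i, xid in enumerate(diseases):
        name = f"disword{i:02d}" + (" disorder" if rng.random() < 0.3 else "")
        g.add_entity(EntityNode(id=xid, name=name, etype="disease"))

    symptoms = [f"sym{i:03d}" for i in range(p.n_symptoms)]
    for i, sid in enumerate(symptoms):
        g.add_entity(EntityNode(id=sid, name=f"symword{i:03d}", etype="symptom"))

    syndromes = [f"syn{i:02d}" for i in range(p.n_syndromes)]
    for i, sid in enumerate(syndromes):
        g.add_entity(EntityNode(id=sid, name=f"synword{i:02d}", etype="syndrome"))

    for did in drugs:
        k = rng.randint(p.min_ingredients_per_drug, min(p.max_ingredients_per_drug, p.n_ingredients))
        for iid in rng.sample(ingredients, k):
            g.add_triple(Triple(did, "contains_ingredient", iid))

    conflict_pairs = []
    for i in range(p.n_ingredients):
        for j in range(i + 1, p.n_ingredients):
            if rng.random() < p.conflict_rate:
                a, b = ingredients[i], ingredients[j]
                if rng.random() < 0.5:
                    g.add_triple(Triple(a, "incompatible_with", b))
                    conflict_pairs.append([a, b, "incompatible_with"])
                else:
                    h, t = (a, b) if rng.random() < 0.5 else (b, a)
                    g.add_triple(Triple(h, "fears", t))
                    conflict_pairs.append([h, t, "fears"])

    for xid in diseases:
        k = rng.randint(p.min_symptoms_per_disease, min(p.max_symptoms_per_disease, p.n_symptoms))
        for sid in rng.sample(symptoms, k):
            g.add_triple(Triple(xid, "has_symptom", sid))
        for _ in range(rng.randint(0, 2)):
            tail = rng.choice(symptoms + diseases)
            if tail != xid:
                g.add_triple(Triple(xid, "contributing_factor", tail))

    for did in drugs:
        for xid in rng.sample(diseases, rng.randint(1, min(3, p.n_diseases))):
            g.add_triple(Triple(did, "indicated_for_disease", xid))
        for sid in rng.sample(syndromes, rng.randint(0, min(2, p.n_syndromes))):
            g.add_triple(Triple(did, "indicated_for_syndrome", sid))
        if rng.random() < 0.15:
            g.add_triple(Triple(did, "contraindicated_for_population", rng.choice(["pregnant", "child"])))
        lo = rng.randint(1, 3)
        hi = lo + rng.randint(1, 6)
        g.add_dosage_rule(DosageRule(did, DEFAULT_POPULATION, float(lo), float(hi), "g"))
        if rng.random() < 0.5:
            clo = max(1, lo // 2)
            g.add_dosage_rule(
                DosageRule(did, "child", float(clo), float(max(clo, hi // 2)), "g")
            )

    drug_conflicts, drug_shared = [], []
    for i, a in enumerate(drugs):
        for b in drugs[i + 1 :]:
            if g.ingredient_conflicts(a, b):
                drug_conflicts.append([a, b])
            if g.shared_ingredients(a, b):
                drug_shared.append([a, b])

    manifest = FixtureManifest(
        seed=seed,
        params=asdict(p),
        counts=g.stats(),
        conflict_ingredient_pairs=conflict_pairs,
        drug_conflict_pairs=drug_conflicts,
        drug_shared_pairs=drug_shared,
    )
    return g, manifest


def lexicon_from_graph(graph: KnowledgeGraph, filler_freq: int = 50) -> Lexicon:
    """Professional dictionary built from graph entity names plus fillers."""
    etype_to_cat = {"disease": "DIS", "symptom": "SYM", "cpm_drug": "ZCY"}
    rows = []
    for node in graph.nodes.values():
        cat = etype_to_cat.get(node.etype)
        if cat is None:
            continue
        rows.append((node.name, 10, cat))
        for alias in node.aliases:
            rows.append((alias, 5, cat))
    for tok in FILLER_TOKENS:
        rows.append((tok, filler_freq, "general"))
    return build_lexicon(rows)


# ------------------------------------------------------------ gen_bio_corpus


def gen_bio_corpus(
    graph: KnowledgeGraph,
    n_sequences: int,
    ambiguity_rate: float = 0.0,
    seed: int = 0,
    n_ambiguous_tokens: int = 6,
) -> tuple[list[BIOSequence], list[list[EntityMention]]]:
    """Template sentences embedding graph entity names, with gold BIO tags.

    With probability ``ambiguity_rate`` an entity slot is filled by a token
    drawn from a shared pool used for both DIS and SYM slots across the
    corpus, so the token's label is not predictable from its identity —
    this caps achievable tagging accuracy below 100%.
    """
    rng = random.Random(seed)
    pools = {
        "DIS": [n.name for n in graph.nodes_of_type("disease")],
        "SYM": [n.name for n in graph.nodes_of_type("symptom")],
        "ZCY": [n.name for n in graph.nodes_of_type("cpm_drug")],
    }
    for label, pool in pools.items():
        if not pool:
            raise FixtureError(f"graph has no entities for label {label}")
        pool.sort()
    ambiguous = [f"ambig{i:02d}" for i in range(n_ambiguous_tokens)]

    corpus: list[BIOSequence] = []
    gold: list[list[EntityMention]] = []
    for _ in range(n_sequences):
        tokens: list[str] = []
        mentions: list[EntityMention] = []
        tokens.extend(rng.choice(FILLER_TOKENS) for _ in range(rng.randint(1, 3)))
        n_slots = rng.randint(1, 3)
        for _ in range(n_slots):
            label = rng.choice(("DIS", "SYM", "ZCY"))
            if label in ("DIS", "SYM") and rng.random() < ambiguity_rate:
                surface = rng.choice(ambiguous)
            else:
                surface = rng.choice(pools[label])
            start = len(tokens)
            words = surface.split()
            tokens.extend(words)
            mentions.append(
                EntityMention(start, start + len(words), label, surface=surface)
            )
            tokens.extend(rng.choice(FILLER_TOKENS) for _ in range(rng.randint(1, 3)))
        corpus.append(BIOSequence(tokens, bio_encode(len(tokens), mentions)))
        gold.append(mentions)
    return corpus, gold


# --------------------------------------------------------------- gen_records

DEFAULT_VIOLATION_RATES = {
    "combined_use": 0.08,
    "repeated_efficacy": 0.10,
    "symptomatic": 0.08,
    "dosage": 0.10,
    "syndrome": 0.10,
}


def _drug_ok_with(graph: KnowledgeGraph, cand: str, chosen: list[str]) -> bool:
    """No taboo pair and no shared ingredient with any already-chosen drug."""
    return all(
        cand != d
        and not graph.ingredient_conflicts(cand, d)
        and not graph.shared_ingredients(cand, d)
        for d in chosen
    )


def _syndrome_ok(graph: KnowledgeGraph, drug: str, syndrome: str | None) -> bool:
    if syndrome is None:
        return True
    _, syns = graph.indications(drug)
    return not syns or syndrome in syns


class _RecordBuilder:
    """Assembles one record with the requested planted violations.

    Raises FixtureError (caught by the caller for a bounded number of
    resamples) when the drawn base context cannot host a planted category.
    """

    def __init__(self, graph: KnowledgeGraph, rng: random.Random, plant: set[str]):
        self.g = graph
        self.rng = rng
        self.plant = plant
        self.drugs: list[str] = []  # distinct drugs, in insertion order
        self.gold: list[dict] = []
        self.all_drugs = sorted(
            n.id for n in graph.nodes_of_type("cpm_drug")
        )
        self.syndrome: str | None = None
        self.sym_drug: str | None = None  # the off-indication drug, if planted

    def _pick(self, pool, pred) -> str | None:
        cands = [c for c in pool if pred(c)]
        return self.rng.choice(cands) if cands else None

    def build(self) -> tuple[MedicalRecord, list[dict]]:
        g, rng = self.g, self.rng
        if "syndrome" in self.plant:
            self.syndrome = rng.choice(sorted(n.id for n in g.nodes_of_type("syndrome")))

        def base_ok(c):
            dis, _ = g.indications(c)
            return (
                dis
                and _drug_ok_with(g, c, self.drugs)
                and _syndrome_ok(g, c, self.syndrome)
            )

        for _ in range(rng.randint(1, 3)):
            c = self._pick(self.all_drugs, base_ok)
            if c is None:
                break
            self.drugs.append(c)
        if not self.drugs:
            raise FixtureError("could not seat any base drug")

        self._plant_combined()
        self._plant_repeated_shared_drug()
        self._plant_symptomatic()
        self._plant_syndrome_drug()

        diagnoses = self._assemble_diagnoses()
        patient = self._draw_patient()
        items, dup_drug = self._assemble_items(patient)
        self._finalize_gold(dup_drug)

        symptoms = []
        if diagnoses:
            pool = sorted(g.disease_symptoms(diagnoses[0]))
            if pool:
                symptoms = rng.sample(pool, min(len(pool), rng.randint(1, 3)))

        record_id = f"rec{rng.randrange(10 ** 8):08d}"
        record = MedicalRecord(
            record_id=record_id,
            items=items,
            diagnoses=diagnoses,
            symptoms=symptoms,
            syndrome=self.syndrome,
            patient=patient,
        )
        record.course_record_text, record.discharge_summary_text = _render_text(
            g, record
        )
        return record, self.gold

    # -- planting helpers ---------------------------------------------------

    def _plant_combined(self):
        if "combined_use" not in self.plant:
            return
        g = self.g

        def ok(c):
            return (
                c not in self.drugs
                and any(g.ingredient_conflicts(c, d) for d in self.drugs)
                and all(not g.shared_ingredients(c, d) for d in self.drugs)
                and g.indications(c)[0]
                and _syndrome_ok(g, c, self.syndrome)
            )

        c = self._pick(self.all_drugs, ok)
        if c is None:
            # try seating a fresh conflicting pair instead
            for a in self.rng.sample(self.all_drugs, len(self.all_drugs)):
                if a in self.drugs or not _drug_ok_with(g, a, self.drugs):
                    continue
                if not (g.indications(a)[0] and _syndrome_ok(g, a, self.syndrome)):
                    continue
                b = self._pick(
                    self.all_drugs,
                    lambda b: b not in self.drugs
                    and b != a
                    and g.ingredient_conflicts(a, b)
                    and not g.shared_ingredients(a, b)
                    and _drug_ok_with(g, b, self.drugs)
                    and g.indications(b)[0]
                    and _syndrome_ok(g, b, self.syndrome),
                )
                if b is not None:
                    self.drugs.extend([a, b])
                    return
            raise FixtureError("combined_use: no conflicting drug fits this record")
        self.drugs.append(c)

    def _plant_repeated_shared_drug(self):
        if "repeated_efficacy" not in self.plant:
            self.repeat_mode = None
            return
        g = self.g
        self.repeat_mode = "duplicate" if self.rng.random() < 0.5 else "shared"
        if self.repeat_mode == "shared":

            def ok(c):
                return (
                    c not in self.drugs
                    and any(g.shared_ingredients(c, d) for d in self.drugs)
                    and all(not g.ingredient_conflicts(c, d) for d in self.drugs)
                    and g.indications(c)[0]
                    and _syndrome_ok(g, c, self.syndrome)
                )

            c = self._pick(self.all_drugs, ok)
            if c is None:
                self.repeat_mode = "duplicate"  # always feasible
            else:
                self.drugs.append(c)

    def _plant_symptomatic(self):
        if "symptomatic" not in self.plant:
            return
        g = self.g
        # the other drugs must each keep an indicated disease OUTSIDE the
        # candidate's indication set, so diagnoses can avoid it entirely
        def ok(c):
            if c in self.drugs or not _drug_ok_with(g, c, self.drugs):
                return False
            cd, _ = g.indications(c)
            if not cd or not _syndrome_ok(g, c, self.syndrome):
                return False
            return all(g.indications(d)[0] - cd for d in self.drugs)

        c = self._pick(self.all_drugs, ok)
        if c is None:
            raise FixtureError("symptomatic: no off-indication drug fits this record")
        self.drugs.append(c)
        self.sym_drug = c
        self.gold.append(
            {"category": "symptomatic", "severity": "warning", "drugs": [c]}
        )

    def _plant_syndrome_drug(self):
        if "syndrome" not in self.plant:
            return
        g = self.g
        assert self.syndrome is not None
        forbidden = g.indications(self.sym_drug)[0] if self.sym_drug else set()

        def ok(c):
            if c in self.drugs or not _drug_ok_with(g, c, self.drugs):
                return False
            dis, syns = g.indications(c)
            return bool(dis - forbidden) and bool(syns) and self.syndrome not in syns

        c = self._pick(self.all_drugs, ok)
        if c is None:
            raise FixtureError("syndrome: no mismatching drug fits this record")
        self.drugs.append(c)
        self.gold.append({"category": "syndrome", "severity": "warning", "drugs": [c]})

    # -- assembly -----------------------------------------------------------

    def _assemble_diagnoses(self) -> list[str]:
        g = self.g
        forbidden = g.indications(self.sym_drug)[0] if self.sym_drug else set()
        diagnoses: list[str] = []
        for d in self.drugs:
            if d == self.sym_drug:
                continue
            choices = sorted(g.indications(d)[0] - forbidden - set(diagnoses))
            if choices:
                diagnoses.append(self.rng.choice(choices))
        if not diagnoses:
            pool = sorted(
                n.id for n in g.nodes_of_type("disease") if n.id not in forbidden
            )
            if not pool:
                raise FixtureError("symptomatic: no disease left for the diagnosis")
            diagnoses.append(self.rng.choice(pool))
        return diagnoses

    def _draw_patient(self) -> PatientProfile:
        rng = self.rng
        if rng.random() < 0.2:
            return PatientProfile(age_years=rng.randint(2, 12))
        if rng.random() < 0.15:
            return PatientProfile(age_years=rng.randint(66, 90))
        return PatientProfile(age_years=rng.randint(18, 60))

    def _assemble_items(self, patient: PatientProfile):
        g, rng = self.g, self.rng
        groups = patient.population_group_ids(g)
        items: list[PrescriptionItem] = []
        dose_victim = None
        if "dosage" in self.plant:
            with_rule = [d for d in self.drugs if g.dosage_rule_lookup(d, groups)]
            if not with_rule:
                raise FixtureError("dosage: no prescribed drug has a dosage rule")
            dose_victim = rng.choice(with_rule)
        for d in self.drugs:
            rule = g.dosage_rule_lookup(d, groups)
            if d == dose_victim:
                assert rule is not None
                if rng.random() < 0.5 and rule.min_daily > 0.5:
                    item = PrescriptionItem(d, rule.min_daily / 2, 1, rule.unit)
                else:
                    item = PrescriptionItem(d, rule.max_daily, 2, rule.unit)
                self.gold.append(
                    {"category": "dosage", "severity": "critical", "drugs": [d]}
                )
            elif rule is not None:
                times = rng.randint(1, 2)
                dose = rng.uniform(rule.min_daily, rule.max_daily) / times
                item = PrescriptionItem(d, round(dose, 3), times, rule.unit)
                if not (rule.min_daily <= item.daily_dose <= rule.max_daily):
                    item = PrescriptionItem(d, rule.min_daily, 1, rule.unit)
            else:
                item = PrescriptionItem(d, 1.0, 1, "g")
            items.append(item)
        dup_drug = None
        if getattr(self, "repeat_mode", None) == "duplicate":
            dup_drug = rng.choice([d for d in self.drugs if d != dose_victim] or self.drugs)
            src = next(i for i in items if i.drug_ref == dup_drug)
            if dup_drug == dose_victim:
                # duplicating the dose victim would double-count its dose gold
                rule = g.dosage_rule_lookup(dup_drug, groups)
                items.append(PrescriptionItem(dup_drug, rule.min_daily, 1, rule.unit))
            else:
                items.append(src)
        rng.shuffle(items)
        return items, dup_drug

    def _finalize_gold(self, dup_drug):
        g = self.g
        # record *all* taboo pairs and shared pairs among the final drug set;
        # by construction these are exactly the planted ones
        ds = sorted(set(self.drugs))
        for i, a in enumerate(ds):
            for b in ds[i + 1 :]:
                if g.ingredient_conflicts(a, b):
                    self.gold.append(
                        {
                            "category": "combined_use",
                            "severity": "critical",
                            "drugs": [a, b],
                        }
                    )
                if g.shared_ingredients(a, b):
                    self.gold.append(
                        {
                            "category": "repeated_efficacy",
                            "severity": "warning",
                            "drugs": [a, b],
                        }
                    )
        if dup_drug is not None:
            self.gold.append(
                {
                    "category": "repeated_efficacy",
                    "severity": "critical",
                    "drugs": [dup_drug],
                }
            )
        if "combined_use" in self.plant and not any(
            a["category"] == "combined_use" for a in self.gold
        ):
            raise FixtureError("combined_use planting left no gold alert")
        if "repeated_efficacy" in self.plant and not any(
            a["category"] == "repeated_efficacy" for a in self.gold
        ):
            raise FixtureError("repeated_efficacy planting left no gold alert")


def _render_text(graph: KnowledgeGraph, record: MedicalRecord) -> tuple[str, str]:
    """Pseudo-language course record and discharge summary naming the
    record's diseases, symptoms, and each prescription item's drug."""
    dis_names = [graph.nodes[d].name for d in record.diagnoses if d in graph.nodes]
    sym_names = [graph.nodes[s].name for s in record.symptoms if s in graph.nodes]
    drug_names = [
        graph.nodes[graph.resolve_name(i.drug_ref)].name
        for i in record.items
        if graph.resolve_name(i.drug_ref)
    ]
    course = "patient reports " + " and ".join(sym_names or ["stable course"])
    if dis_names:
        course += " noted " + " and ".join(dis_names)
    discharge = "treatment given " + " and ".join(drug_names or ["follow up"])
    discharge += " discharged stable"
    return course, discharge


def record_gold_mentions(
    graph: KnowledgeGraph, record: MedicalRecord
) -> tuple[list[str], list[EntityMention]]:
    """Tokens and gold mentions over the joined text sections, matching how
    the review pipeline consumes free text."""
    text = " ".join(
        t
        for t in (record.course_record_text, record.discharge_summary_text)
        if t
    )
    tokens = text.split()
    names = {}
    for etype, label in (("disease", "DIS"), ("symptom", "SYM"), ("cpm_drug", "ZCY")):
        for node in graph.nodes_of_type(etype):
            names[tuple(node.name.split())] = label
    mentions = []
    i = 0
    max_len = max((len(k) for k in names), default=1)
    while i < len(tokens):
        hit = None
        for width in range(min(max_len, len(tokens) - i), 0, -1):
            key = tuple(tokens[i : i + width])
            if key in names:
                hit = (width, names[key])
                break
        if hit:
            width, label = hit
            mentions.append(
                EntityMention(i, i + width, label, surface=" ".join(tokens[i : i + width]))
            )
            i += width
        else:
            i += 1
    return tokens, mentions


def gen_records(
    graph: KnowledgeGraph,
    n_records: int,
    violation_rates: dict | None = None,
    seed: int = 0,
    manifest: FixtureManifest | None = None,
    max_retries: int = 60,
) -> tuple[list[MedicalRecord], FixtureManifest]:
    """Generate records with per-category planted violations and gold alerts.

    Each category is planted independently with its requested probability.
    The returned manifest maps record_id to its gold alert list (category,
    severity, sorted drug ids) and to gold text mentions.  Raises
    FixtureError naming the category when a requested violation is
    impossible under the graph.
    """
    rates = dict(DEFAULT_VIOLATION_RATES)
    if violation_rates:
        unknown = set(violation_rates) - set(CATEGORIES)
        if unknown:
            raise FixtureError(f"unknown violation categories: {sorted(unknown)}")
        rates.update(violation_rates)
    for cat, rate in rates.items():
        if not (0 <= rate <= 1):
            raise FixtureError(f"violation rate for {cat} must be in [0, 1]")

    # upfront feasibility
    have_conflict = any(
        graph.ingredient_conflicts(a, b)
        for i, a in enumerate(sorted(n.id for n in graph.nodes_of_type("cpm_drug")))
        for b in sorted(n.id for n in graph.nodes_of_type("cpm_drug"))[i + 1 :]
    )
    if rates["combined_use"] > 0 and not have_conflict:
        raise FixtureError("combined_use violations requested but the graph has no conflicting drug pair")
    if rates["syndrome"] > 0 and not graph.nodes_of_type("syndrome"):
        raise FixtureError("syndrome violations requested but the graph has no syndromes")

    rng = random.Random(seed)
    out = manifest or FixtureManifest(seed=seed, params={})
    out.params.setdefault("violation_rates", rates)
    out.params.setdefault("n_records", n_records)
    records: list[MedicalRecord] = []
    seen_ids: set[str] = set()
    for _ in range(n_records):
        plant = {c for c in CATEGORIES if rng.random() < rates[c]}
        record = gold = None
        for _attempt in range(max_retries):
            try:
                record, gold = _RecordBuilder(graph, rng, plant).build()
            except FixtureError:
                continue
            if record.record_id in seen_ids:
                continue
            break
        if record is None:
            raise FixtureError(
                f"could not realise planted categories {sorted(plant)} "
                f"after {max_retries} attempts"
            )
        seen_ids.add(record.record_id)
        records.append(record)
        out.gold_alerts[record.record_id] = sorted(
            gold, key=lambda a: (a["category"], a["severity"], a["drugs"])
        )
        _, mentions = record_gold_mentions(graph, record)
        out.gold_mentions[record.record_id] = [
            {"start": m.start, "end": m.end, "label": m.label, "surface": m.surface}
            for m in mentions
        ]
    return records, out


def gold_alert_keys(gold_alerts: list[dict]) -> set[tuple]:
    """Comparison keys (category, severity, sorted drug tuple) for one record."""
    return {
        (a["category"], a["severity"], tuple(sorted(a["drugs"])))
        for a in gold_alerts
    }


def report_alert_keys(report) -> set[tuple]:
    """Warning/critical alert keys of a ReviewReport, same shape as gold."""
    return {
        (a.category, a.severity, tuple(sorted(a.drugs)))
        for a in report.alerts
        if a.severity != "info"
    }
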