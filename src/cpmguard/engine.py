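"""The five prescription checks and the aggregated review report.

A medical record (structured prescription items, diagnoses, symptoms,
syndrome, patient profile — or free text from which those are recovered
by the NER front end) is screened against the knowledge-graph rule base:

* combined_use     — taboo ingredient pairs between co-prescribed products
* repeated_efficacy — duplicate products or products sharing active
                      ingredients (hidden duplication)
* symptomatic      — product not indicated for any recorded or inferred
                      disease
* dosage           — daily dose outside the population-appropriate range
* syndrome         — product's indicated syndromes exclude the recorded
                      TCM syndrome pattern

Severity ladder (an artifact convention — the source monitoring framework
names no severities): critical for taboo combinations, duplicate products
and out-of-range doses; warning for shared-ingredient overlap, indication
and syndrome mismatches; info for missing or unlinkable data, which must
never fail a prescription silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .kg import DEFAULT_POPULATION, DosageRule, KnowledgeGraph, Triple

CATEGORIES = ("combined_use", "repeated_efficacy", "symptomatic", "dosage", "syndrome")
SEVERITIES = ("info", "warning", "critical")
_SEV_RANK = {s: i for i, s in enumerate(SEVERITIES)}

#: age cutoffs for derived population groups, in years (configurable)
CHILD_AGE_MAX = 14
ELDERLY_AGE_MIN = 65


class EngineError(ValueError):
    pass


@dataclass(frozen=True)
class PrescriptionItem:
    drug_ref: str  # name or entity id
    single_dose: float = 1.0
    times_per_day: int = 1
    unit: str = "g"

    def __post_init__(self):
        if self.single_dose <= 0:
            raise EngineError(f"item {self.drug_ref!r}: single_dose must be positive")
        if self.times_per_day < 1 or int(self.times_per_day) != self.times_per_day:
            raise EngineError(
                f"item {self.drug_ref!r}: times_per_day must be a positive integer"
            )

    @property
    def daily_dose(self) -> float:
        return self.single_dose * self.times_per_day


@dataclass(frozen=True)
class PatientProfile:
    age_years: float = 40.0
    pregnant: bool = False
    lactating: bool = False
    hepatic_impairment: bool = False
    renal_impairment: bool = False

    def __post_init__(self):
        if self.age_years < 0:
            raise EngineError("age_years must be non-negative")

    def population_group_names(
        self, child_age_max: float = CHILD_AGE_MAX, elderly_age_min: float = ELDERLY_AGE_MIN
    ) -> set[str]:
        groups = set()
        if self.age_years < child_age_max:
            groups.add("child")
        if self.age_years >= elderly_age_min:
            groups.add("elderly")
        for flag in ("pregnant", "lactating", "hepatic_impairment", "renal_impairment"):
            if getattr(self, flag):
                groups.add(flag)
        return groups

    def population_group_ids(self, graph: KnowledgeGraph, **cutoffs) -> set[str]:
        """Resolve the derived group names against the graph's nodes."""
        ids = set()
        for name in self.population_group_names(**cutoffs):
            nid = graph.resolve_name(name)
            if nid is not None and graph.nodes[nid].etype == "population_group":
                ids.add(nid)
        return ids


@dataclass
class MedicalRecord:
    record_id: str
    items: list[PrescriptionItem] = field(default_factory=list)
    diagnoses: list[str] = field(default_factory=list)  # disease names or ids
    symptoms: list[str] = field(default_factory=list)
    syndrome: str | None = None
    patient: PatientProfile = field(default_factory=PatientProfile)
    course_record_text: str = ""
    discharge_summary_text: str = ""

    def __post_init__(self):
        if not self.items and not (self.course_record_text or self.discharge_summary_text):
            raise EngineError(
                f"record {self.record_id!r}: needs prescription items or text sections"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "MedicalRecord":
        return cls(
            record_id=d["record_id"],
            items=[
                PrescriptionItem(
                    drug_ref=i["drug_ref"],
                    single_dose=i.get("single_dose", 1.0),
                    times_per_day=i.get("times_per_day", 1),
                    unit=i.get("unit", "g"),
                )
                for i in d.get("items", [])
            ],
            diagnoses=list(d.get("diagnoses", [])),
            symptoms=list(d.get("symptoms", [])),
            syndrome=d.get("syndrome"),
            patient=PatientProfile(**d.get("patient", {})),
            course_record_text=d.get("course_record_text", ""),
            discharge_summary_text=d.get("discharge_summary_text", ""),
        )

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "items": [
                {
                    "drug_ref": i.drug_ref,
                    "single_dose": i.single_dose,
                    "times_per_day": i.times_per_day,
                    "unit": i.unit,
                }
                for i in self.items
            ],
            "diagnoses": list(self.diagnoses),
            "symptoms": list(self.symptoms),
            "syndrome": self.syndrome,
            "patient": {
                "age_years": self.patient.age_years,
                "pregnant": self.patient.pregnant,
                "lactating": self.patient.lactating,
                "hepatic_impairment": self.patient.hepatic_impairment,
                "renal_impairment": self.patient.renal_impairment,
            },
            "course_record_text": self.course_record_text,
            "discharge_summary_text": self.discharge_summary_text,
        }


@dataclass(frozen=True)
class Alert:
    category: str
    severity: str
    drugs: tuple[str, ...]
    evidence: tuple
    message: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise EngineError(f"unknown alert category {self.category!r}")
        if self.severity not in SEVERITIES:
            raise EngineError(f"unknown severity {self.severity!r}")
        if self.severity != "info" and not self.evidence:
            raise EngineError(
                f"{self.severity} alert in {self.category!r} requires evidence"
            )

    def to_dict(self) -> dict:
        def _ev(e):
            if isinstance(e, Triple):
                return {"head": e.head, "relation": e.relation, "tail": e.tail}
            if isinstance(e, DosageRule):
                return {
                    "drug": e.drug,
                    "population": e.population,
                    "min_daily": e.min_daily,
                    "max_daily": e.max_daily,
                    "unit": e.unit,
                }
            if isinstance(e, (tuple, list)):
                return [_ev(x) for x in e]
            return e

        return {
            "category": self.category,
            "severity": self.severity,
            "drugs": list(self.drugs),
            "evidence": [_ev(e) for e in self.evidence],
            "message": self.message,
        }


@dataclass
class ReviewReport:
    record_id: str
    alerts: list[Alert]
    verdicts: dict[str, str]  # category -> "pass" | "flagged"
    severity_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "alerts": [a.to_dict() for a in sorted_alerts(self.alerts)],
            "verdicts": {c: self.verdicts[c] for c in CATEGORIES},
            "severity_counts": {s: self.severity_counts[s] for s in SEVERITIES},
            "summary": self.summary(),
        }

    def summary(self) -> str:
        lines = [f"record {self.record_id}:"]
        for c in CATEGORIES:
            lines.append(f"  {c}: {self.verdicts[c]}")
        for a in sorted_alerts(self.alerts):
            lines.append(f"  [{a.severity}] {a.category}: {a.message}")
        return "\n".join(lines)

    @property
    def has_critical(self) -> bool:
        return self.severity_counts.get("critical", 0) > 0


def sorted_alerts(alerts) -> list[Alert]:
    return sorted(
        alerts, key=lambda a: (CATEGORIES.index(a.category), -_SEV_RANK[a.severity], a.drugs)
    )


# ---------------------------------------------------------- item resolution


def resolve_items(
    items: list[PrescriptionItem], graph: KnowledgeGraph
) -> tuple[list[tuple[PrescriptionItem, str]], list[PrescriptionItem]]:
    """Split items into (item, drug_id) pairs and unlinkable leftovers."""
    linked, unlinked = [], []
    for item in items:
        nid = graph.resolve_name(item.drug_ref)
        if nid is not None and graph.nodes[nid].etype == "cpm_drug":
            linked.append((item, nid))
        else:
            unlinked.append(item)
    return linked, unlinked


def _unlinked_alerts(category: str, unlinked: list[PrescriptionItem]) -> list[Alert]:
    return [
        Alert(
            category=category,
            severity="info",
            drugs=(item.drug_ref,),
            evidence=(),
            message=f"drug {item.drug_ref!r} not found in the rule base; skipped",
        )
        for item in unlinked
    ]


# ----------------------------------------------------------------- 5 checks


def check_combined_use(
    items: list[PrescriptionItem], graph: KnowledgeGraph
) -> list[Alert]:
    """Pairwise taboo screening over all prescribed products.

    Each unordered pair of distinct drugs whose ingredient cross-product
    hits ``incompatible_with`` or ``fears`` yields one critical alert with
    the conflicting triples as evidence; n drugs are screened as the union
    of their n(n-1)/2 pairs.
    """
    linked, unlinked = resolve_items(items, graph)
    alerts = _unlinked_alerts("combined_use", unlinked)
    drug_ids = sorted({d for _, d in linked})
    for i, a in enumerate(drug_ids):
        for b in drug_ids[i + 1 :]:
            evidence = graph.conflict_evidence(a, b)
            if evidence:
                names = (graph.nodes[a].name, graph.nodes[b].name)
                alerts.append(
                    Alert(
                        category="combined_use",
                        severity="critical",
                        drugs=(a, b),
                        evidence=tuple(evidence),
                        message=(
                            f"taboo combination: {names[0]} + {names[1]} "
                            f"({len(evidence)} conflicting ingredient pair(s))"
                        ),
                    )
                )
    return alerts


def check_repeated_efficacy(
    items: list[PrescriptionItem], graph: KnowledgeGraph, k_shared: int = 1
) -> list[Alert]:
    """Duplicate products (critical) and shared-ingredient overlap (warning)."""
    if k_shared < 1:
        raise EngineError("k_shared must be >= 1")
    linked, unlinked = resolve_items(items, graph)
    alerts = _unlinked_alerts("repeated_efficacy", unlinked)
    counts: dict[str, int] = {}
    for _, d in linked:
        counts[d] = counts.get(d, 0) + 1
    for d in sorted(counts):
        if counts[d] > 1:
            alerts.append(
                Alert(
                    category="repeated_efficacy",
                    severity="critical",
                    drugs=(d,),
                    evidence=(("duplicate_item", counts[d]),),
                    message=f"{graph.nodes[d].name} prescribed {counts[d]} times",
                )
            )
    drug_ids = sorted(counts)
    for i, a in enumerate(drug_ids):
        for b in drug_ids[i + 1 :]:
            shared = graph.shared_ingredients(a, b)
            if len(shared) >= k_shared:
                alerts.append(
                    Alert(
                        category="repeated_efficacy",
                        severity="warning",
                        drugs=(a, b),
                        evidence=tuple(sorted(shared)),
                        message=(
                            f"{graph.nodes[a].name} and {graph.nodes[b].name} share "
                            f"{len(shared)} active ingredient(s)"
                        ),
                    )
                )
    return alerts


def check_symptomatic(
    items: list[PrescriptionItem],
    record: MedicalRecord,
    graph: KnowledgeGraph,
    min_overlap: int = 2,
) -> list[Alert]:
    """Does each product treat something the patient actually has?

    Candidate diseases are the recorded diagnoses when present; otherwise
    they are inferred from the recorded symptoms through the
    disease-symptom graph, requiring at least ``min_overlap`` shared
    symptoms (one shared symptom is weak evidence when one disease maps to
    dozens of symptoms).
    """
    linked, unlinked = resolve_items(items, graph)
    alerts = _unlinked_alerts("symptomatic", unlinked)
    candidates: set[str] = set()
    for ref in record.diagnoses:
        nid = graph.resolve_name(ref)
        if nid is not None and graph.nodes[nid].etype == "disease":
            candidates.add(nid)
    if not candidates:
        symptom_ids = []
        for ref in record.symptoms:
            nid = graph.resolve_name(ref)
            symptom_ids.append(nid if nid is not None else ref)
        candidates = {d for d, _ in graph.diseases_for_symptoms(symptom_ids, min_overlap)}
    if not candidates:
        alerts.append(
            Alert(
                category="symptomatic",
                severity="info",
                drugs=(),
                evidence=(),
                message="no diagnosis recorded and none inferable from symptoms",
            )
        )
        return alerts
    for d in sorted({d for _, d in linked}):
        diseases, _ = graph.indications(d)
        if not diseases:
            alerts.append(
                Alert(
                    category="symptomatic",
                    severity="info",
                    drugs=(d,),
                    evidence=(),
                    message=f"no indication data for {graph.nodes[d].name}",
                )
            )
        elif not (diseases & candidates):
            alerts.append(
                Alert(
                    category="symptomatic",
                    severity="warning",
                    drugs=(d,),
                    evidence=tuple(
                        Triple(d, "indicated_for_disease", x) for x in sorted(diseases)
                    ),
                    message=(
                        f"{graph.nodes[d].name} is not indicated for any recorded "
                        f"or inferred disease"
                    ),
                )
            )
    return alerts


def check_dosage(
    items: list[PrescriptionItem],
    patient: PatientProfile,
    graph: KnowledgeGraph,
    child_age_max: float = CHILD_AGE_MAX,
    elderly_age_min: float = ELDERLY_AGE_MIN,
) -> list[Alert]:
    """Daily dose vs the population-appropriate rule; bounds are inclusive."""
    linked, unlinked = resolve_items(items, graph)
    alerts = _unlinked_alerts("dosage", unlinked)
    groups = patient.population_group_ids(
        graph, child_age_max=child_age_max, elderly_age_min=elderly_age_min
    )
    for item, d in linked:
        rule = graph.dosage_rule_lookup(d, groups)
        if rule is None:
            alerts.append(
                Alert(
                    category="dosage",
                    severity="info",
                    drugs=(d,),
                    evidence=(),
                    message=f"no dosage rule for {graph.nodes[d].name}",
                )
            )
            continue
        if item.unit != rule.unit:
            alerts.append(
                Alert(
                    category="dosage",
                    severity="warning",
                    drugs=(d,),
                    evidence=((rule, item.unit),),
                    message=(
                        f"{graph.nodes[d].name}: unit mismatch "
                        f"({item.unit!r} vs rule {rule.unit!r}), not evaluated"
                    ),
                )
            )
            continue
        dose = item.daily_dose
        if dose < rule.min_daily or dose > rule.max_daily:
            alerts.append(
                Alert(
                    category="dosage",
                    severity="critical",
                    drugs=(d,),
                    evidence=((rule, dose),),
                    message=(
                        f"{graph.nodes[d].name}: daily dose {dose:g}{rule.unit} "
                        f"outside [{rule.min_daily:g}, {rule.max_daily:g}]{rule.unit} "
                        f"({rule.population})"
                    ),
                )
            )
    return alerts


def check_syndrome(
    items: list[PrescriptionItem], record: MedicalRecord, graph: KnowledgeGraph
) -> list[Alert]:
    """Syndrome differentiation: the product should match the diagnosed
    TCM syndrome pattern, not only the disease name."""
    linked, unlinked = resolve_items(items, graph)
    alerts = _unlinked_alerts("syndrome", unlinked)
    if not record.syndrome:
        alerts.append(
            Alert(
                category="syndrome",
                severity="info",
                drugs=(),
                evidence=(),
                message="no TCM syndrome recorded; differentiation not assessable",
            )
        )
        return alerts
    syn_id = graph.resolve_name(record.syndrome)
    for d in sorted({d for _, d in linked}):
        _, syndromes = graph.indications(d)
        if not syndromes:
            alerts.append(
                Alert(
                    category="syndrome",
                    severity="info",
                    drugs=(d,),
                    evidence=(),
                    message=f"no syndrome data for {graph.nodes[d].name}",
                )
            )
        elif syn_id not in syndromes:
            alerts.append(
                Alert(
                    category="syndrome",
                    severity="warning",
                    drugs=(d,),
                    evidence=tuple(
                        Triple(d, "indicated_for_syndrome", x) for x in sorted(syndromes)
                    ),
                    message=(
                        f"{graph.nodes[d].name} is not indicated for syndrome "
                        f"{record.syndrome!r}"
                    ),
                )
            )
    return alerts


# -------------------------------------------------------------- full review


def _populate_from_text(record: MedicalRecord, graph, model, lexicon) -> MedicalRecord:
    from .ner import link_mentions, tag_text

    if model is None:
        raise EngineError(
            f"record {record.record_id!r} has no structured fields and no "
            f"tagger model was supplied"
        )
    text = " ".join(
        t for t in (record.course_record_text, record.discharge_summary_text) if t
    )
    mentions = link_mentions(tag_text(model, text, lexicon), graph)
    items = list(record.items)
    diagnoses = list(record.diagnoses)
    symptoms = list(record.symptoms)
    for m in mentions:
        ref = m.entity_id if m.entity_id is not None else m.surface
        if m.label == "ZCY" and not record.items:
            items.append(PrescriptionItem(drug_ref=ref))
        elif m.label == "DIS" and not record.diagnoses:
            diagnoses.append(ref)
        elif m.label == "SYM" and not record.symptoms:
            symptoms.append(ref)
    return MedicalRecord(
        record_id=record.record_id,
        items=items,
        diagnoses=diagnoses,
        symptoms=symptoms,
        syndrome=record.syndrome,
        patient=record.patient,
        course_record_text=record.course_record_text,
        discharge_summary_text=record.discharge_summary_text,
    )


def review_record(
    record: MedicalRecord,
    graph: KnowledgeGraph,
    model=None,
    lexicon=None,
    k_shared: int = 1,
    min_overlap: int = 2,
    child_age_max: float = CHILD_AGE_MAX,
    elderly_age_min: float = ELDERLY_AGE_MIN,
) -> ReviewReport:
    """Run all five checks on one record and assemble the review report.

    When structured fields are missing and text sections are present, the
    NER front end recovers drugs (ZCY), diagnoses (DIS), and symptoms
    (SYM) from the text first.  Deterministic given inputs and model.
    """
    has_text = bool(record.course_record_text or record.discharge_summary_text)
    missing = not record.items or not (record.diagnoses or record.symptoms)
    if has_text and missing and (model is not None or not record.items):
        record = _populate_from_text(record, graph, model, lexicon)
    alerts: list[Alert] = []
    alerts += check_combined_use(record.items, graph)
    alerts += check_repeated_efficacy(record.items, graph, k_shared=k_shared)
    alerts += check_symptomatic(record.items, record, graph, min_overlap=min_overlap)
    alerts += check_dosage(
        record.items,
        record.patient,
        graph,
        child_age_max=child_age_max,
        elderly_age_min=elderly_age_min,
    )
    alerts += check_syndrome(record.items, record, graph)
    verdicts = {c: "pass" for c in CATEGORIES}
    counts = {s: 0 for s in SEVERITIES}
    for a in alerts:
        counts[a.severity] += 1
        if _SEV_RANK[a.severity] >= _SEV_RANK["warning"]:
            verdicts[a.category] = "flagged"
    return ReviewReport(
        record_id=record.record_id,
        alerts=sorted_alerts(alerts),
        verdicts=verdicts,
        severity_counts=counts,
    )


def load_records(path) -> list[MedicalRecord]:
    """JSON Lines, one MedicalRecord per line."""
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(MedicalRecord.from_dict(json.loads(line)))
            except (json.JSONDecodeError, KeyError, TypeError, EngineError) as exc:
                raise EngineError(f"records line {lineno}: {exc}") from exc
    return records


def save_records(records: list[MedicalRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps(r.to_dict(), ensure_ascii=False) + "\n")
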