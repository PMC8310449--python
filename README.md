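# cpmguard

Prescription-safety monitoring for **Chinese patent medicines (CPM)** —
manufactured multi-herb formulations — built on a typed knowledge graph that
serves as the rule base for automated prescription review.

Clinical prescribing of CPM carries risks that a relational formulary
handles poorly: the classical pairwise herb taboos (the *eighteen
contraindications* and *nineteen fears*) live at the **ingredient** level,
so conflicts between finished products only emerge by joining each product's
ingredient set against a taboo-pair table; hidden duplication arises when two
differently-named products share active ingredients; dose limits depend on
the population (children, the elderly, pregnancy, lactation, hepatic or
renal impairment); and a product should match not only the diagnosed
disease but the patient's TCM syndrome pattern (辨证论治). `cpmguard` is
aimed at pharmacists, prescription-review developers, and pharmacovigilance
researchers who need these checks to be executable, auditable rules.

## What it does

1. **Knowledge-graph rule base** (`cpmguard.kg`): typed entities
   (`cpm_drug`, `ingredient`, `disease`, `symptom`, `syndrome`,
   `population_group`) and relation triples with enforced signatures
   (`contains_ingredient`, `incompatible_with`, `fears`,
   `indicated_for_disease`, `indicated_for_syndrome`, `has_symptom`, …)
   plus per-population dosage rules. JSON Lines interchange, full
   validation with line numbers, and the graph queries the checks consume.

2. **NER front end** (`cpmguard.ner`): unigram maximum-probability word
   segmentation over a professional dictionary (exact dynamic program over
   word frequencies), BIO tagging with three entity categories — `DIS`
   (disease), `SYM` (symptom), `ZCY` (CPM) — a pluggable sequence tagger
   whose default backend is an averaged structured perceptron with
   BIO-constrained Viterbi decoding, entity linking (exact / alias / fuzzy),
   and strict span-level precision / recall / F1 evaluation with macro and
   micro averages.

3. **Rule engine** (`cpmguard.engine`): five checks per record —
   *combined use* (cross-product ingredient pairs hitting a taboo relation;
   an n-drug prescription is screened as all n(n−1)/2 pairs),
   *repeated efficacy* (duplicate products, shared active ingredients),
   *symptomatic administration* (product vs recorded or symptom-inferred
   diseases), *dosage* (daily dose vs the population-appropriate rule), and
   *syndrome differentiation* — aggregated into a `ReviewReport` with
   graph-path evidence and a pass/flagged verdict per category.

4. **Synthetic fixtures** (`cpmguard.fixtures`): deterministic generators
   for graphs, BIO corpora, and medical-record batches with planted,
   bookkept violations, so the whole pipeline is testable without any
   proprietary pharmacopoeia or hospital data.

## Worked example

```python
from cpmguard import (gen_kg, review_record, MedicalRecord,
                      PrescriptionItem, PatientProfile)

graph, manifest = gen_kg(seed=7)          # synthetic rule base, 214 nodes
a, b = manifest.drug_conflict_pairs[0]    # two products with a planted taboo
rec = MedicalRecord(
    "demo-001",
    items=[PrescriptionItem(a, single_dose=2, times_per_day=2),
           PrescriptionItem(b, single_dose=1, times_per_day=3)],
    diagnoses=[sorted(graph.indications(a)[0])[0]],
    patient=PatientProfile(age_years=6),
)
print(review_record(rec, graph).summary())
```

prints

```
record demo-001:
  combined_use: flagged
  repeated_efficacy: pass
  symptomatic: flagged
  dosage: flagged
  syndrome: pass
  [critical] combined_use: taboo combination: drugword00 + drugword11 (1 conflicting ingredient pair(s))
  [warning] symptomatic: drugword11 is not indicated for any recorded or inferred disease
  [critical] dosage: drugword00: daily dose 4g outside [1, 1]g (child)
  [info] syndrome: no TCM syndrome recorded; differentiation not assessable
```

The two products are flagged because one ingredient of each forms a stored
`incompatible_with` pair (the evidence triple is attached to the alert);
the second product treats none of the recorded diagnoses; and a 4 g daily
dose exceeds the child-specific rule selected for the 6-year-old patient.
Severities: `critical` for taboo combinations, duplicates, and dose range
violations; `warning` for shared-ingredient, indication, and syndrome
mismatches; `info` for missing data — an unlinkable drug never fails a
prescription silently.

## Command line

```bash
cpmguard fixtures --out-dir demo --seed 3          # demo graph/corpus/records
cpmguard kg validate demo/graph.jsonl              # exit 1 + line numbers on errors
cpmguard kg stats demo/graph.jsonl
cpmguard check --graph demo/graph.jsonl --records demo/records.jsonl \
               --output reports.json               # exit 2 iff any critical alert
cpmguard tag --graph demo/graph.jsonl --model model.json \
             --lexicon demo/lexicon.tsv --records demo/records.jsonl \
             --output mentions.jsonl
cpmguard eval --gold gold.jsonl --predicted mentions.jsonl
```

All commands accept `--config config.yaml` (flags win over file values);
unknown config keys are rejected so runs are reproducible from
`(config, inputs, seed)`.

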