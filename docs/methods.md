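# Methods

This note documents the models and procedures implemented in `cpmguard`,
the design choices made where the design was genuinely open, and what the
synthetic fixtures do and do not establish about behaviour on real data.

## The rule base as a typed graph

Entities are nodes of six types — CPM products, herbal ingredients,
diseases, symptoms, TCM syndromes, and population groups — and knowledge
is stored as relation triples whose endpoint types are enforced at insert
time (e.g. `contains_ingredient: cpm_drug → ingredient`,
`has_symptom: disease → symptom`). Two relations encode the classical
pairwise herb taboos:

* `incompatible_with` (the "eighteen contraindications") is semantically
  symmetric; it is stored once per unordered pair and every query treats
  it symmetrically.
* `fears` (the "nineteen fears") is traditionally directed — "A fears B".
  The direction is preserved in storage and in alert evidence, but
  conflict *detection* ignores it: a safety screen should not depend on
  which side of a taboo pair a prescription happens to contain.

The taboo lists name herb varieties, not finished products. Product-level
conflict is therefore **defined** here as the existence of any
cross-product ingredient pair carrying either taboo relation; multi-drug
prescriptions are screened strictly pairwise (the union over all drug
pairs), with no emergent three-way rules, because ingredient-level
composition is the only mechanism the domain specifies.

Dosage rules attach to `(drug, population)` with a `default_adult`
sentinel. Lookup returns the most specific applicable rule under a fixed
priority — pregnant > lactating > child > elderly > hepatic impairment >
renal impairment > default — matched on the population node's canonical
name. The order is a package convention chosen for determinism (more
vulnerable groups win); no ordering is prescribed by the domain. Age
cutoffs default to child < 14 years and elderly ≥ 65 years and are
configurable. Toxicity is not modelled as a distinct relation; it enters
only implicitly through dose limits.

Unknown symptom ids passed to the disease-inference query are skipped with
a logged warning rather than raising, because NER output legitimately
contains unlinkable mentions and the pipeline must degrade gracefully.
Duplicate triples are ignored idempotently.

## Word segmentation

Free text is reduced to atomic tokens — characters for ideographic
scripts, whitespace tokens otherwise — and segmented into dictionary words
by maximising the sum of log unigram probabilities
`Σ log(freq(w) / total)` over the professional dictionary, computed by
dynamic programming over the token-position graph. Any single token absent
from the dictionary is usable with a pseudo-frequency of 0.5 against the
same total, which guarantees a path exists for arbitrary input while
preferring dictionary words (every true entry has frequency ≥ 1). Ties are
broken by preferring fewer words, then the lexicographically smaller word
list. The implementation scores paths with exact rational arithmetic
(maximising the product of `freq/total` fractions, equivalent to the log
objective), so tie-breaking is exact and the DP can be compared
bit-for-bit against exhaustive enumeration; the test suite verifies global
optimality on every token string of length ≤ 8 over a toy lexicon.

Duplicate dictionary entries merge by summing frequencies; on a category
conflict the first non-`general` category wins (categories are a feature
aid, not a hard label, so the choice only perturbs one tagging feature).

## Sequence tagging

Entity spans use BIO tags over three categories (`DIS`, `SYM`, `ZCY`).
Decoding repairs a dangling `I-X` (one not preceded by `B-X`/`I-X` of the
same category) to `B-X`, so any tag stream yields a valid, non-overlapping
mention set; encode∘decode is the identity on valid mention sets.

The default tagger backend is an **averaged structured perceptron**: a
first-order conditional sequence model with per-token features (token
identity, neighbouring tokens, dictionary category, and position-in-word
from the segmenter) plus tag-transition weights, decoded by Viterbi search
under hard BIO constraints (`I-X` may only follow `B-X`/`I-X`). Training
shuffles with a caller-supplied seed and is fully deterministic given
(corpus, seed); 8 epochs suffice for the desk-scale corpora used here.
The backend registry accepts plugins, so a contextual-encoder tagger can
be substituted behind the same `train_tagger`/`tag_text` contract without
touching the rest of the pipeline. No GPU path is provided.

Entity linking tries the exact canonical name, then aliases, then a fuzzy
match (normalised difflib ratio, threshold 0.85, configurable) restricted
to nodes of the etype implied by the label. The threshold has no
domain-prescribed value; 0.85 tolerates roughly one edit in a six-character
name while rejecting unrelated names, and unresolved mentions surface as
`unlinked` rather than being dropped.

## Evaluation metrics

NER evaluation is **strict span-level**: a prediction counts only if
(start, end, label) all match a gold mention — the conservative CoNLL
convention, since no partial-credit scheme is prescribed for this task.
Per-class precision/recall/F1 are reported on the 0–100 scale with the 0
convention for empty denominators, alongside the **macro** average (the
unweighted mean over the three classes — this is the aggregation that
reproduces the summary column of the reference benchmark table) and the
**micro** average from pooled counts. F1 is always computed from
unrounded counts. One cell of the reference table (the symptom-class F1)
is not the harmonic mean of its printed P/R — most plausibly an artifact
of pooling before rounding on the original corpus — so the package makes
no attempt to reproduce that cell, and the acceptance targets use only the
internally consistent cells.

## The five checks and the report

Severities are a package convention (the monitoring framework itself names
none): `critical` for taboo combinations, duplicate products, and doses
outside the applicable range (bounds inclusive); `warning` for
shared-ingredient overlap (threshold `k_shared`, default 1 shared
ingredient), indication mismatch, syndrome mismatch, and unit mismatches
(reported but not evaluated); `info` for anything that cannot be assessed
— unlinkable drugs, missing rules, missing diagnosis/syndrome. Info alerts
never flag a category, so missing data is visible but does not fail a
prescription.

For the symptomatic check, candidate diseases are the recorded diagnoses
when present; otherwise they are inferred from recorded symptoms via the
disease–symptom graph with a minimum overlap of 2 shared symptoms
(default, configurable). A single shared symptom is deliberately treated
as too weak to support an off-indication warning — one disease maps to
dozens of symptoms — so single-symptom records degrade to `info`.

A review runs all five checks and always reports all five categories; a
category verdict is `flagged` iff it holds at least one warning or
critical alert. When structured fields are missing and text sections are
present, the NER front end populates them first (ZCY → prescription items
with unknown dose, DIS → diagnoses, SYM → symptoms). Reports serialize
with sorted keys so a batch run is byte-deterministic; the batch CLI exits
2 iff any critical alert exists.

## Synthetic fixtures

The fixture generators stand in for the proprietary pharmacopoeia,
guideline corpus, and hospital records that real deployments would use.
They use a whitespace pseudo-language (`drugword07`, `disword10 disorder`,
…) so all tests are locale-independent; real ideographic text exercises
the same code paths through the character tokenizer but is only reached
via user-supplied data.

Default graph conditions: 30 products with 2–8 ingredients each drawn
from 90; taboo edges planted per unordered ingredient pair at rate 0.005
(dense enough that conflicting product pairs exist, sparse enough that
conflict-free 5-drug prescriptions remain constructible); 20 diseases with
3–12 symptoms each from a pool of 60; 1–3 indicated diseases and 0–2
syndromes per product; a default-adult dosage rule for every product and a
child-specific rule for about half.

Record generation plants each violation category independently with a
requested probability (defaults 8–10% per category, a plausible order of
magnitude for irrational-prescription screening; no empirical rate is
available for the real record stream). Planted violations are constructed
**not to interfere**: a drug added to create a taboo pair is verified not
to also share ingredients with the rest of the prescription, diagnoses are
chosen to cover every non-planted drug while avoiding the off-indication
drug's entire indication set, and syndrome-mismatch planting constrains
the other drugs to match (or lack) the recorded syndrome. Records that
cannot host their drawn categories are resampled; genuinely impossible
requests (e.g. conflicts requested on a conflict-free graph) raise an
error naming the category. In consequence the generator's gold alerts
coincide exactly with the warning/critical alerts the engine should
produce, which is what the recovery tests assert (100% precision and
recall over ≥ 500 records × 3 seeds). Base records leave the syndrome
field empty unless a syndrome violation is planted, so the syndrome
category contributes gold alerts only when planted.

What passing these tests shows: the checks implement their definitions
exactly (they match independent brute-force re-derivations), the pipeline
is deterministic, and recovery is complete when records link exactly to
the rule base. What they do not show: robustness to real clinical prose,
spelling variation beyond the fuzzy-link threshold, incomplete rule bases,
or tagger accuracy on natural language — the degradation test (alert
recall is non-increasing as synthetic tag noise grows from 0 to 20%) probes
the failure direction but not real-text error distributions.

## Problem sizes and numerical choices

Test and acceptance workloads are desk-scale by design: graphs of 15–50
products, record batches of 25–600, corpora of 80–200 sentences, 1000-case
property sweeps. Segmentation uses exact rationals (no float ties);
evaluation metrics are floats with a 1e-9 comparison slack in invariant
tests; Viterbi breaks score ties by a fixed tag order; all generators take
explicit integer seeds and `random.Random` instances so identical inputs
give byte-identical artifacts.

## Known limitations

* No Chinese–Western drug interaction rules and no hepatic/renal dose
  adjustment formulas: impairment states act only as population flags.
* The dose check compares daily totals only, and only when units match
  exactly; there is no unit conversion.
* Entity linking is string-based; no embedding or ontology alignment.
* The default tagger is a linear model; state-of-the-art contextual
  accuracy requires plugging in a pretrained backend.
* The text path recovers prescription items without doses, so dosage
  violations are only detectable from structured records.
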