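# clinanno

Hybrid semantic annotator for Spanish medical text — clinical trial
announcements, eligibility criteria and clinical case reports.  It combines
a dictionary (lemma + variant lexicon with UMLS/SNOMED CT normalization),
hand-crafted rules (HeidelTime-style temporal patterns, NegEx/ConText-style
negation, speculation and context triggers, medication term grammars) and a
pluggable token-classification model backend behind one pipeline.

## What it annotates

| Layer | Labels |
|---|---|
| UMLS entities | ANAT, CHEM, DISO, PROC, DEVI, GENE, PHYS, LIVB, ACTI |
| Temporal | Date, Duration, Frequency, Time, Age |
| Medication | Dose (dose/concentration/strength), Route, Form |
| Miscellaneous | CONC, Food_or_Drink, Observation_or_Finding, Quantifier_or_Qualifier, Result_or_Value |
| Cues | Neg_cue, Spec_cue |

Attributes (typed flags bound to one entity): Negated, Speculated,
Contraindicated, History_of, Family_History_of, Future, Hypothetical,
Patient, Family_member, Other, Age.  Negation and speculation are marked at
the **concept level**: in *"Los pacientes no habían recibido tratamiento
antibiótico"* only the concept *tratamiento antibiótico* receives
`Negated`; the subject does not, and no scope span is emitted.

Entity-level evaluation ships with the package: strict match (a true
positive requires identical span and label) and relaxed match (same label,
≥ 1 character overlap, one-to-one greedy pairing), with

P = TP/(TP+FP),  R = TP/(TP+FN),  F1 = 2PR/(P+R)

micro-averaged over labels, plus pairwise-F1 inter-annotator agreement and
corpus statistics.

## Worked example

```python
from clinanno import Resources, run_pipeline, toy_lexicon

res = Resources(lexicon=toy_lexicon())
doc = run_pipeline("Los pacientes no habían recibido tratamiento antibiótico",
                   resources=res)
for e in doc.entities:
    print(e.id, e.label, repr(e.surface), e.codes)
for a in doc.attributes:
    print(a.id, a.type, "->", doc.entity_by_id(a.target).surface)
```

prints

```
T1 LIVB 'pacientes' [('UMLS', 'C0030705')]
T2 Neg_cue 'no' []
T3 PROC 'tratamiento antibiótico' [('UMLS', 'C0338237')]
A1 Negated -> tratamiento antibiótico
A2 Patient -> pacientes
```

— the treatment concept is negated, the patients are the (non-negated)
experiencer, and both dictionary entities carry their UMLS CUIs.

From the shell:

```
clinanno annotate input_dir/ --out-dir out --format ann   # BRAT .txt/.ann
clinanno score gold_dir/ pred_dir/                        # P/R/F1 table
clinanno gen-fixtures --seed 1 --n-docs 10 --out-dir fx   # synthetic corpus
```

The annotator is configurable through a flat `key = value` file
(`--config`): backend (`dict`/`model`/`hybrid`), normalization scheme
(`umls`/`snomed`/`none`), per-layer toggles, excluded semantic groups,
scope window sizes.

## Layout

* `src/clinanno/core.py` — document model, normalization, segmentation
* `src/clinanno/lexicon.py` — dictionary NER and concept normalization
* `src/clinanno/temporal.py`, `medication.py`, `misc_entities.py` — rule taggers
* `src/clinanno/negspec.py`, `context_attrs.py` — cues, scopes, attributes
* `src/clinanno/model_backend.py` — adapter contract, BIO decoding, hybrid merge
* `src/clinanno/formats.py` — BIO / BRAT standoff / JSON
* `src/clinanno/evaluation.py` — strict/relaxed scoring, IAA, statistics
* `src/clinanno/pipeline.py`, `cli.py` — orchestration and command line
* `src/clinanno/fixtures.py` — synthetic lexicon/corpus and augmentation
* `src/clinanno/data/` — editable rule tables and term lists

See `docs/methods.md` for the method description and design rationale.
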