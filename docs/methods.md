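# Methods

## Overview

clinanno annotates Spanish medical text in three stages.  Stage 1
normalizes the text, segments it into sentences and tokens, and recognizes
UMLS-group entities with a dictionary, a token-classification model, or a
hybrid merge of both.  Stage 2 applies rule-based taggers for temporal
expressions, medication information, miscellaneous clinical entities and
negation/speculation cues, then assigns concept-level attributes
(Negated/Speculated, event temporality, experiencer, Contraindicated,
Age).  Stage 3 serializes to JSON, BRAT standoff or CoNLL-style BIO.

Entities live in five layers (umls, temporal, medication, misc, cues).
Within one layer spans never partially overlap; identical spans may
co-exist in the umls layer when a term belongs to several semantic groups;
spans from different layers may nest (a Dose inside a PROC phrase).  All
offsets are 0-based, end-exclusive Unicode code points — the BRAT
convention — so standoff files round-trip bit-exactly.

## Text normalization and segmentation

Normalization is restricted to same-length, single-character substitutions
(typographic quotes, no-break/thin spaces, soft hyphens and dashes).  This
keeps raw and normalized offsets identical, removing the need for an
offset map; it is idempotent and length-preserving by construction.  The
exact character set is a packaged table (`core.DEFAULT_SUBSTITUTIONS`) and
can be overridden.

Segmentation is an injected provider contract: any callable returning
sentences and tokens with verified offsets, optional lemma and coarse POS.
The shipped default is a dependency-free rule tokenizer (sentence breaks
at `.!?` + whitespace; tokens are decimal numbers, word runs or single
punctuation marks; the lemma is the lower-cased surface).  A spaCy wrapper
with the same contract is provided for installations that have a Spanish
model; all shipped tests run on the rule tokenizer.

## Dictionary NER and normalization

The lexicon records, per entry: lemma, surface variants, one or more UMLS
semantic groups, UMLS CUIs and SNOMED CT codes, and an abbreviation flag.
Matching is greedy left-to-right longest match over token n-grams, bounded
by sentences (entities never cross sentence boundaries in this annotation
scheme), trying the surface sequence before the lemma sequence (surface is
the more specific evidence; it wins ties at equal length).  Lookup keys
are lower-cased with Spanish vowel accents stripped (clinical text is
inconsistent about accents; ñ is preserved as a distinct letter);
abbreviation entries are matched case-sensitively and unfolded so that
"IV" the route never collides with lower-case text.  A term in several
groups emits one co-located entity per group; no sense disambiguation is
attempted.  Group exclusion (e.g. dropping ACTI) filters emitted entities
*after* matching, so excluding one group can never change the spans found
for another — the alternative (skipping excluded entries during the scan)
would let an excluded long match unblock nested matches of other groups.

Normalization restricts an entity's codes to one scheme (UMLS CUIs or
SNOMED CT); unknown surfaces simply get an empty code list.

## Temporal tagger

Rules are regular expressions over sentence text (editable table:
pattern, class, priority) covering the TimeML classes Date, Duration,
Frequency (TimeML "set") and Time, plus Age.  A packaged Spanish number
grammar (digits with decimal comma/dot, number words to ninety-nine with
"y"-compounds) feeds the patterns, so "dos horas" parses like "2 horas".
Overlaps are resolved deterministically: higher priority, then longer
span, then smaller start.

Age disambiguation: "N años" is Age only when an age trigger ("edad",
"mayores/menores (de)") occurs within a ±4-token window; otherwise it
demotes to Duration.  The span is the number-through-unit ("18 años"), not
the trigger.  "pre-/post-" prefixed expressions map to Date by default and
to Time when the head is a time-of-day word; they are kept as Date/Time
rather than merged into a separate prefixed class.  The Duration span for
"durante dos horas" is "dos horas" (the preposition is context, not
content), while the Frequency span for "cada ocho horas" includes "cada"
(the cue is what makes the expression a frequency).  No calendar-value
normalization is performed — only span and class.

## Medication tagger

Dose (dose, concentration and strength merged into one class) is a number
— digits with Spanish decimal comma or dot, a number word, or a simple
range ("10-20") treated as a single clinical fact — followed by a unit,
optionally compound ("mg/kg", "UI/m2").  The unit list includes "%"
concentrations and per-surface-area denominators.  Routes and dosage
forms are list lookups (starter lists modeled on the Spanish Medicines
Agency Nomenclátor structure, shipped as editable files) with gender and
plural inflections expanded at load; route abbreviations (IV, SC, VO…)
match case-sensitively, and a preceding "vía" is absorbed into the Route
span ("vía oral").  Within the medication layer, Dose wins over Route/Form
tokens it covers.

## Miscellaneous entities

Result_or_Value is comparator + number + optional unit ("< 3 UNL",
"≥ 50%"); a bare number never matches.  Quantifier_or_Qualifier covers
quantity phrases ("al menos 4") and a starter list of severity/laterality/
extent adjectives.  CONC, Food_or_Drink and Observation_or_Finding are
recognized by the dictionary matcher restricted to those groups.

Cross-layer resolution (applied in pipeline order temporal → medication →
misc): when a Dose and a Result_or_Value overlap, the Dose wins — unless
the Result begins with an explicit comparator, which signals a lab value
("≥ 50%") rather than a prescription ("125 mg").  The comparator
exception is this package's resolution of the otherwise contradictory
requirements that "%" be a dose unit and that comparator expressions be
results.

## Negation and speculation

Trigger tables (editable TSV) translate the NegEx/ConText cue inventory to
Spanish: cues with a polarity (negation/speculation) and direction
(pre/post), pseudo-triggers ("no solo") that suppress the cue they
contain, and termination terms ("pero", "aunque") that end a scope early.
Trigger matching lower-cases but does not strip accents, keeping the
conditional "si" distinct from "sí".  Cue detection is greedy longest
match; detected cues become Neg_cue/Spec_cue entities.

A cue's scope runs forward from the cue end (backward for post-cues) to
the earliest of: sentence end, first termination term, or a window of 6
tokens (NegEx heritage; configurable).  Whether the original tools bound
scope by window or only by terminators is not documented; the window is
therefore explicit configuration.  Scopes are computation artifacts, not
annotations: an eligible entity (ANAT, CHEM, DEVI, DISO, GENE, LIVB,
PHYS, PROC) **fully contained** in a scope receives Negated or Speculated
— containment, not mere overlap, because marking is concept-level.  With
several covering scopes the nearest cue wins, and negation beats
speculation at equal distance.

## Context attributes

Event temporality (on DISO/PROC/PHYS): trigger phrases for History_of
("antecedentes de"), Family_History_of ("antecedentes familiares de"),
Hypothetical ("en caso de", "si") and Future, plus a toggleable heuristic
that treats simple-future verb forms (-rá/-rán) as Future triggers — trial
prose announces interventions in the future tense, and the suffix is a
cheap, precise signal in this genre.  The nearest in-sentence trigger
within an 8-token window wins; at equal distance Family_History_of beats
History_of and Hypothetical beats Future.  One temporality attribute per
entity, maximum.  Hypothetical and Family_History_of are fully supported
in the rule path even though they are rare in practice.

Experiencer (on LIVB): exactly one of Patient / Family_member / Other for
terms in the patient, kin and role lists respectively; LIVB terms in none
of the lists (species, viruses) carry no experiencer rather than a guessed
default.

Contraindicated (on CHEM/PROC): forward window after a contraindication
trigger ("contraindicación a/para", "contraindicado/a").  A negation word
immediately before the trigger ("sin contraindicación a") suppresses the
attribute — without this, exclusion-criteria phrasing would invert the
meaning.

Age attribute: LIVB terms that denote an age group ("adultos", "niños",
"lactantes") receive the Age attribute; they do not additionally receive
an Age temporal entity (the span is a living being, not a time
expression).

## Model backend and hybrid merge

The model contract is deliberately narrow: given sentences as token
lists, return one BIO label and one confidence per input token.  Subword
tokenization (WordPiece/BPE) is the adapter's private business under the
first-subword convention, so the core never sees subwords and stays
model-agnostic.  BIO decoding repairs invalid transitions (`I-X` after
`O` or after a different type becomes `B-X`).  The hybrid merge defaults
to model-first: span-identical same-label pairs merge with the model span
keeping the dictionary's codes; on conflicts the model entity wins;
dictionary-only groups (default {ACTI}) are always retained, since no
model is trained for them.  The conflict rule is configurable
(`dictionary_first`) because there is no single right answer.  The
shipped test adapter is a deterministic lookup table; real transformer
adapters plug in behind the same contract as optional extras.

## Formats

BRAT standoff uses the exact line grammar `T{n}\t{Label} {start}
{end}\t{surface}` for entities, `A{n}\t{Type} T{m}` for (binary)
attributes and `N{n}\tReference T{m} {scheme}:{code}\t{surface}` for
normalizations; reading verifies every span against the text and
round-trips are lossless modulo identifier renumbering.  Discontinuous
entities are not supported.  BIO files are two-column TSV with blank
lines between sentences; entities not aligned to token boundaries are
snapped outward with a logged warning, and co-located duplicate spans
keep one label (BIO cannot express the rest).  The JSON schema
(`doc_id`, `text`, `entities[]`, `attributes[]`) is normative for this
package.

## Evaluation

Strict match: TP iff (start, end, label) identical, multiset semantics.
Relaxed match: same label and at least one character of overlap, paired
one-to-one greedily by descending overlap (ties by smaller gold start,
then predicted start) — the published relaxed criterion is underspecified,
so this definition is normative here.  P, R and F1 use the zero
convention (all 0 when a denominator is 0).  Micro-averages pool TP/FP/FN
over labels, chosen over macro because of heavy class imbalance.
Inter-annotator agreement is the pairwise F-measure; TP is symmetric and
FP/FN swap under argument exchange, so F1 is symmetric.  Attributes are
scored as (entity span, attribute type) units, strict on the span, so
entity and attribute scores are directly comparable.  Per-document means
are floored to two decimals using integer arithmetic (86 389 entities /
1 200 docs → 71.99; 16 590 attributes / 1 200 docs → 13.82).

## Synthetic data

The fixture generator exists so every component is testable without
downloads or licensed resources.  The toy lexicon (24 entries) mirrors
the *structure* of a real medical lexicon — multiword variants, a
multi-code entry, an abbreviation pair ("intravenoso"/"IV" sharing a
CUI), one entry per semantic group — with plausible but synthetic codes.
The corpus generator assembles documents from a fixed template grammar
(26 sentence templates) drawing one template per annotation layer plus
random extras, deterministically per seed; every document carries exact
gold entities and attributes.  Two templates are verbatim canonical
examples (the concept-level negation sentence and the contraindication
sentence).  The synonym-replacement augmentation swaps entity surfaces
for lexicon variants sharing a CUI and recomputes all offsets, preserving
labels and counts.

Because the templates use only vocabulary the rules cover, the pipeline
reproduces the gold corpus with strict micro F1 = 1.0 — this
self-consistency is the central end-to-end test.  It demonstrates that
the pipeline implements its own annotation scheme exactly; it does
**not** estimate performance on real clinical text, whose vocabulary
breadth, misspellings, ambiguous scopes and discontinuous mentions the
generator deliberately does not simulate.

## Problem sizes and numerical choices

The shipped checks use a 50-document synthetic corpus for the end-to-end
self-consistency, 200 randomized instances per oracle-equivalence suite
(dictionary matcher vs exhaustive n-gram enumeration; strict scorer vs
multiset intersection; scope assignment vs brute-force containment) and
100 documents for format round-trips — sizes at which the randomized
suites explore the combinatorics thoroughly while the whole test run
stays around a second.  All randomness is seeded; the pipeline itself is
fully deterministic (ties in every resolution step are broken by explicit
ordering rules, never by hash or insertion order).

## Known limitations

No word-sense disambiguation of normalization codes; no fuzzy/approximate
dictionary matching; no temporal relation extraction or calendar
anchoring; no syntax-based scope resolution or double-negation handling;
no cross-sentence experiencer propagation; discontinuous entities are not
representable.  The packaged trigger tables and term lists are faithful-
by-construction starter sets, intended to be edited for real deployments,
not replicas of any proprietary resource.
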