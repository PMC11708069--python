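"""ConText-style attributes: event temporality (History_of,
Family_History_of, Future, Hypothetical), experiencer (Patient,
Family_member, Other), Contraindicated, and the Age attribute on
age-denoting living-being entities.

Temporality applies to DISO/PROC/PHYS entities; the experiencer is marked
only on LIVB entities whose term appears in the patient/kin/role lists
(other LIVB terms carry no experiencer).  Future detection combines trigger
phrases with a toggleable simple-future suffix heuristic (verbs in -rá /
-rán), since clinical-trial prose leans heavily on the future tense.
A negation cue immediately before a contraindication trigger ("sin
contraindicación a") suppresses Contraindicated.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import Attribute, Document, Entity, Sentence, strip_accents
from .resources import iter_data_lines, load_term_set

TEMPORALITY_LABELS = frozenset({"DISO", "PROC", "PHYS"})
CONTRA_LABELS = frozenset({"CHEM", "PROC"})

#: Tie-break precedence (lower rank wins at equal distance):
#: Family_History_of > History_of; Hypothetical > Future.
_TEMPORALITY_RANK = {
    "Family_History_of": 0,
    "History_of": 1,
    "Hypothetical": 2,
    "Future": 3,
}

DEFAULT_CONTEXT_WINDOW = 8

_CONTRA_SUPPRESSORS = {"sin", "no"}


@dataclass(frozen=True)
class ContextTrigger:
    tokens: tuple[str, ...]
    attribute: str
    direction: str


def load_context_triggers(path=None) -> list[ContextTrigger]:
    if path is None:
        lines = list(iter_data_lines("context_triggers.tsv"))
    else:
        with open(path, encoding="utf-8") as fh:
            lines = [
                l.rstrip("\n")
                for l in fh
                if l.strip() and not l.lstrip().startswith("#")
            ]
    out = []
    for line in lines:
        pattern, attribute, direction = line.split("\t")
        out.append(
            ContextTrigger(tuple(pattern.lower().split()), attribute, direction)
        )
    return out


@dataclass
class ExperiencerLists:
    patient: set[str]
    kin: set[str]
    role: set[str]


def load_experiencer_lists() -> ExperiencerLists:
    return ExperiencerLists(
        patient={strip_accents(t) for t in load_term_set("experiencer_patient.txt")},
        kin={strip_accents(t) for t in load_term_set("experiencer_kin.txt")},
        role={strip_accents(t) for t in load_term_set("experiencer_role.txt")},
    )


def load_age_terms() -> set[str]:
    return {strip_accents(t) for t in load_term_set("age_livb_terms.txt", gender=True)}


# ---------------------------------------------------------------------------
# Trigger matching helpers
# ---------------------------------------------------------------------------


def _trigger_hits(
    sent: Sentence, triggers: list[ContextTrigger]
) -> list[tuple[int, int, ContextTrigger]]:
    """(first_token_index, last_token_index_exclusive, trigger) matches."""
    keys = [t.surface.lower() for t in sent.tokens]
    hits = []
    for trig in triggers:
        n = len(trig.tokens)
        for i in range(len(keys) - n + 1):
            if tuple(keys[i : i + n]) == trig.tokens:
                hits.append((i, i + n, trig))
    return hits


def _entity_token_range(ent: Entity, sent: Sentence) -> tuple[int, int] | None:
    idx = [
        i for i, t in enumerate(sent.tokens) if t.start < ent.end and ent.start < t.end
    ]
    if not idx:
        return None
    return idx[0], idx[-1] + 1


def _sentence_of(doc: Document, ent: Entity) -> Sentence | None:
    for sent in doc.sentences:
        if sent.start <= ent.start and ent.end <= sent.end:
            return sent
    return None


def _future_suffix_hits(sent: Sentence) -> list[tuple[int, int, ContextTrigger]]:
    hits = []
    for i, tok in enumerate(sent.tokens):
        s = tok.surface.lower()
        if len(s) > 3 and (s.endswith("rá") or s.endswith("rán")):
            hits.append((i, i + 1, ContextTrigger((s,), "Future", "pre")))
    return hits


def _assign_by_distance(
    doc: Document,
    entities: list[Entity],
    hits_per_sentence,
    eligible_labels: frozenset,
    window: int,
    rank: dict[str, int] | None = None,
) -> list[Attribute]:
    out = []
    for ent in entities:
        if ent.label not in eligible_labels:
            continue
        sent = _sentence_of(doc, ent)
        if sent is None:
            continue
        rng = _entity_token_range(ent, sent)
        if rng is None:
            continue
        ei, ej = rng
        candidates = []
        for ti, tj, trig in hits_per_sentence.get(id(sent), []):
            if trig.direction == "pre" and tj <= ei and ei - tj <= window:
                candidates.append((ei - tj, trig))
            elif trig.direction == "post" and ti >= ej and ti - ej <= window:
                candidates.append((ti - ej, trig))
        if not candidates:
            continue
        if rank is None:
            candidates.sort(key=lambda c: c[0])
        else:
            candidates.sort(key=lambda c: (c[0], rank.get(c[1].attribute, 99)))
        out.append(Attribute(id="", type=candidates[0][1].attribute, target=ent.id))
    return out


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def assign_temporality(
    doc: Document,
    entities: list[Entity],
    triggers: list[ContextTrigger] | None = None,
    window: int = DEFAULT_CONTEXT_WINDOW,
    future_suffix: bool = True,
) -> list[Attribute]:
    """Temporality attributes on DISO/PROC/PHYS entities.

    The nearest in-window trigger in the same sentence wins; at equal
    distance Family_History_of beats History_of and Hypothetical beats
    Future.  At most one temporality attribute per entity.
    """
    if triggers is None:
        triggers = load_context_triggers()
    temp = [t for t in triggers if t.attribute in _TEMPORALITY_RANK]
    hits = {}
    for sent in doc.sentences:
        h = _trigger_hits(sent, temp)
        if future_suffix:
            h += _future_suffix_hits(sent)
        hits[id(sent)] = h
    return _assign_by_distance(
        doc, entities, hits, TEMPORALITY_LABELS, window, _TEMPORALITY_RANK
    )


def assign_experiencer(
    doc: Document,
    entities: list[Entity],
    lists: ExperiencerLists | None = None,
) -> list[Attribute]:
    """Experiencer on human-denoting LIVB entities: Patient (default for
    patient terms), Family_member (kin terms), Other (personnel/role
    terms).  LIVB terms in none of the lists stay bare."""
    lists = lists or load_experiencer_lists()
    out = []
    for ent in entities:
        if ent.label != "LIVB":
            continue
        key = strip_accents(ent.surface.lower())
        if key in lists.patient:
            etype = "Patient"
        elif key in lists.kin:
            etype = "Family_member"
        elif key in lists.role:
            etype = "Other"
        else:
            continue
        out.append(Attribute(id="", type=etype, target=ent.id))
    return out


def assign_contraindicated(
    doc: Document,
    entities: list[Entity],
    triggers: list[ContextTrigger] | None = None,
    window: int = DEFAULT_CONTEXT_WINDOW,
) -> list[Attribute]:
    """Contraindicated on CHEM/PROC entities within the forward window of a
    contraindication trigger.  A negation word immediately before the
    trigger ("sin contraindicación a") suppresses the assignment."""
    if triggers is None:
        triggers = load_context_triggers()
    contra = [t for t in triggers if t.attribute == "Contraindicated"]
    hits = {}
    for sent in doc.sentences:
        kept = []
        for ti, tj, trig in _trigger_hits(sent, contra):
            if ti > 0 and sent.tokens[ti - 1].surface.lower() in _CONTRA_SUPPRESSORS:
                continue
            kept.append((ti, tj, trig))
        hits[id(sent)] = kept
    return _assign_by_distance(doc, entities, hits, CONTRA_LABELS, window)


def assign_age_attr(
    entities: list[Entity], age_terms: set[str] | None = None
) -> list[Attribute]:
    """Age attribute on LIVB entities whose term denotes an age group
    ("adultos", "niños")."""
    if age_terms is None:
        age_terms = load_age_terms()
    out = []
    for ent in entities:
        if ent.label != "LIVB":
            continue
        if strip_accents(ent.surface.lower()) in age_terms:
            out.append(Attribute(id="", type="Age", target=ent.id))
    return out
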