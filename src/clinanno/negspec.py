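"""Negation and speculation: cue detection and concept-level attribute
assignment (NegEx/ConText adapted to Spanish).

Cues (Neg_cue, Spec_cue) are emitted as entities; the governed region
(scope) is computed per cue but is *not* annotated as a span — entities
fully inside a scope receive a ``Negated`` or ``Speculated`` attribute
instead.  Pseudo-triggers ("no solo") suppress the cue they contain;
termination terms ("pero") end a scope early; scopes never cross sentence
boundaries and are bounded by a token window (default 6, NegEx heritage).

Trigger tables are editable TSV data files: pattern, polarity
(negation|speculation|any), direction (pre|post), kind
(cue|pseudo|termination).  Trigger matching lower-cases but does not strip
accents, so the conditional "si" stays distinct from "sí".
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import Attribute, Document, Entity, Sentence
from .resources import iter_data_lines

#: Entity labels eligible for Negated/Speculated (concept-level marking on
#: UMLS entities).
NEGSPEC_LABELS = frozenset(
    {"ANAT", "CHEM", "DEVI", "DISO", "GENE", "LIVB", "PHYS", "PROC"}
)

DEFAULT_MAX_WINDOW = 6

_POLARITIES = {"negation", "speculation", "any"}
_DIRECTIONS = {"pre", "post"}
_KINDS = {"cue", "pseudo", "termination"}


@dataclass(frozen=True)
class Trigger:
    tokens: tuple[str, ...]
    polarity: str
    direction: str
    kind: str


@dataclass
class Scope:
    """Character region governed by one cue, inside one sentence."""

    cue: Entity
    polarity: str
    start: int
    end: int

    def contains(self, ent: Entity) -> bool:
        return self.start <= ent.start and ent.end <= self.end


def load_triggers(path=None) -> list[Trigger]:
    if path is None:
        lines = list(iter_data_lines("negspec_triggers.tsv"))
    else:
        with open(path, encoding="utf-8") as fh:
            lines = [
                l.rstrip("\n")
                for l in fh
                if l.strip() and not l.lstrip().startswith("#")
            ]
    triggers = []
    for line in lines:
        pattern, polarity, direction, kind = line.split("\t")
        if polarity not in _POLARITIES or direction not in _DIRECTIONS or kind not in _KINDS:
            raise ValueError(f"malformed trigger line: {line!r}")
        toks = tuple(pattern.lower().split())
        if not toks:
            raise ValueError("empty trigger pattern")
        triggers.append(Trigger(toks, polarity, direction, kind))
    return triggers


def _tok_key(surface: str) -> str:
    return surface.lower()


def _matches_at(sent: Sentence, i: int, triggers: list[Trigger]) -> list[Trigger]:
    """Triggers whose token sequence matches at token index ``i``,
    longest first."""
    hits = []
    keys = [_tok_key(t.surface) for t in sent.tokens]
    for trig in triggers:
        n = len(trig.tokens)
        if i + n <= len(keys) and tuple(keys[i : i + n]) == trig.tokens:
            hits.append(trig)
    return sorted(hits, key=lambda t: -len(t.tokens))


def detect_cues(doc: Document, triggers: list[Trigger] | None = None) -> list[Entity]:
    """Detect Neg_cue/Spec_cue entities.

    Greedy left-to-right, longest trigger wins at each position; a span
    matching a pseudo trigger consumes its tokens and emits nothing.
    """
    if triggers is None:
        triggers = load_triggers()
    active = [t for t in triggers if t.kind in {"cue", "pseudo"}]
    out: list[Entity] = []
    for sent in doc.sentences:
        i = 0
        while i < len(sent.tokens):
            hits = _matches_at(sent, i, active)
            if not hits:
                i += 1
                continue
            best_len = len(hits[0].tokens)
            best = [t for t in hits if len(t.tokens) == best_len]
            # pseudo wins ties at equal length: it exists to suppress
            trig = next((t for t in best if t.kind == "pseudo"), best[0])
            start = sent.tokens[i].start
            end = sent.tokens[i + len(trig.tokens) - 1].end
            if trig.kind == "cue":
                out.append(
                    Entity(
                        id="",
                        label="Neg_cue" if trig.polarity == "negation" else "Spec_cue",
                        start=start,
                        end=end,
                        surface=doc.text[start:end],
                        source="rules",
                    )
                )
            i += len(trig.tokens)
    return out


def _cue_token_range(cue: Entity, sent: Sentence) -> tuple[int, int]:
    idx = [
        i for i, t in enumerate(sent.tokens) if t.start < cue.end and cue.start < t.end
    ]
    if not idx:
        raise ValueError("cue does not lie inside the sentence")
    return idx[0], idx[-1] + 1


def _termination_starts(sent: Sentence, triggers: list[Trigger]) -> list[int]:
    terms = [t for t in triggers if t.kind == "termination"]
    return [i for i in range(len(sent.tokens)) if _matches_at(sent, i, terms)]


def compute_scope(
    cue: Entity,
    sentence: Sentence,
    triggers: list[Trigger],
    max_window: int = DEFAULT_MAX_WINDOW,
    direction: str = "pre",
    polarity: str = "negation",
) -> Scope:
    """Scope of one cue within its sentence.

    pre-cue: forward from the cue end to the earliest of sentence end, the
    first termination trigger, or ``max_window`` tokens.  post-cue is the
    mirror image, ending at the cue start.
    """
    ci, cj = _cue_token_range(cue, sentence)
    term_idx = _termination_starts(sentence, triggers)
    if direction == "pre":
        hi = min(len(sentence.tokens), cj + max_window)
        for t in sorted(term_idx):
            if cj <= t < hi:
                hi = t
                break
        if hi <= cj:
            return Scope(cue, polarity, cue.end, cue.end)
        return Scope(cue, polarity, cue.end, sentence.tokens[hi - 1].end)
    lo = max(0, ci - max_window)
    for t in sorted(term_idx, reverse=True):
        if lo <= t < ci:
            lo = t + 1
            break
    if lo >= ci:
        return Scope(cue, polarity, cue.start, cue.start)
    return Scope(cue, polarity, sentence.tokens[lo].start, cue.start)


def compute_scopes(
    doc: Document,
    cues: list[Entity],
    triggers: list[Trigger] | None = None,
    max_window: int = DEFAULT_MAX_WINDOW,
) -> list[Scope]:
    """Scopes for all detected cues, using each cue's trigger direction.

    A cue whose surface matches several trigger rows uses the first row with
    the matching polarity.
    """
    if triggers is None:
        triggers = load_triggers()
    scopes = []
    for cue in cues:
        sent = next(
            (s for s in doc.sentences if s.start <= cue.start and cue.end <= s.end),
            None,
        )
        if sent is None:
            continue
        polarity = "negation" if cue.label == "Neg_cue" else "speculation"
        key = tuple(cue.surface.lower().split())
        direction = next(
            (
                t.direction
                for t in triggers
                if t.kind == "cue" and t.tokens == key and t.polarity == polarity
            ),
            "pre",
        )
        scopes.append(
            compute_scope(cue, sent, triggers, max_window, direction, polarity)
        )
    return scopes


def assign_negspec(entities: list[Entity], scopes: list[Scope]) -> list[Attribute]:
    """Concept-level Negated/Speculated assignment.

    An eligible entity fully inside a scope is flagged per the cue polarity;
    with several covering scopes the nearest cue wins, and negation beats
    speculation at equal distance.  At most one attribute per entity.
    """
    out: list[Attribute] = []
    for ent in entities:
        if ent.label not in NEGSPEC_LABELS:
            continue
        covering = [s for s in scopes if s.contains(ent)]
        if not covering:
            continue

        def dist(s: Scope) -> int:
            if s.cue.end <= ent.start:
                return ent.start - s.cue.end
            return s.cue.start - ent.end

        covering.sort(key=lambda s: (dist(s), 0 if s.polarity == "negation" else 1))
        winner = covering[0]
        out.append(
            Attribute(
                id="",
                type="Negated" if winner.polarity == "negation" else "Speculated",
                target=ent.id,
            )
        )
    return out
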