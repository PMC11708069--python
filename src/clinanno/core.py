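"""Document/annotation data model, offset-preserving text normalization and
segmentation.

Offsets everywhere in this package are 0-based, end-exclusive, and counted in
Unicode code points — the same convention BRAT standoff files use, so spans
written to ``.ann`` files are bit-exact.

Entities live in *layers* (``umls``, ``temporal``, ``medication``, ``misc``,
``cues``).  Within one layer entities may not partially overlap; co-located
(identical-span) entities are permitted inside the ``umls`` layer for terms
that belong to several semantic groups, and spans from different layers may
nest freely (e.g. a ``Dose`` inside a ``PROC`` phrase).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Protocol

# ---------------------------------------------------------------------------
# Closed vocabularies
# ---------------------------------------------------------------------------

#: UMLS semantic groups annotated as entity labels.
UMLS_GROUPS = frozenset(
    {"ANAT", "CHEM", "DISO", "PROC", "DEVI", "GENE", "PHYS", "LIVB", "ACTI"}
)

TEMPORAL_LABELS = frozenset({"Date", "Duration", "Frequency", "Time", "Age"})
MEDICATION_LABELS = frozenset({"Dose", "Route", "Form"})
CUE_LABELS = frozenset({"Neg_cue", "Spec_cue"})
MISC_LABELS = frozenset(
    {
        "CONC",
        "Food_or_Drink",
        "Observation_or_Finding",
        "Quantifier_or_Qualifier",
        "Result_or_Value",
    }
)

#: Full closed entity-label vocabulary.
ENTITY_LABELS = frozenset(
    UMLS_GROUPS | TEMPORAL_LABELS | MEDICATION_LABELS | CUE_LABELS | MISC_LABELS
)

#: Closed attribute-type vocabulary.
ATTRIBUTE_TYPES = frozenset(
    {
        "Age",
        "Negated",
        "Speculated",
        "Contraindicated",
        "History_of",
        "Family_History_of",
        "Future",
        "Hypothetical",
        "Patient",
        "Family_member",
        "Other",
    }
)

ENTITY_SOURCES = frozenset({"dictionary", "rules", "model", "gold"})

#: Annotation layers, in pipeline application order.
LAYERS = ("umls", "temporal", "medication", "misc", "cues")


def layer_of(label: str) -> str:
    """Return the annotation layer a label belongs to."""
    if label in UMLS_GROUPS:
        return "umls"
    if label in TEMPORAL_LABELS:
        return "temporal"
    if label in MEDICATION_LABELS:
        return "medication"
    if label in CUE_LABELS:
        return "cues"
    if label in MISC_LABELS:
        return "misc"
    raise ValueError(f"unknown entity label: {label!r}")


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass
class Token:
    surface: str
    start: int
    end: int
    lemma: str | None = None
    pos: str | None = None


@dataclass
class Sentence:
    start: int
    end: int
    tokens: list[Token] = field(default_factory=list)


@dataclass
class Entity:
    """A labeled text span.

    ``codes`` holds normalization codes as ``(scheme, code)`` pairs with
    scheme in {"UMLS", "SNOMEDCT"}.  ``source`` records which component
    produced the span.
    """

    id: str
    label: str
    start: int
    end: int
    surface: str
    codes: list[tuple[str, str]] = field(default_factory=list)
    source: str = "rules"
    score: float | None = None

    @property
    def layer(self) -> str:
        return layer_of(self.label)

    def overlaps(self, other: "Entity") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Attribute:
    """A typed boolean flag bound to exactly one entity (by entity id)."""

    id: str
    type: str
    target: str


@dataclass
class Document:
    doc_id: str
    raw_text: str
    text: str
    sentences: list[Sentence] = field(default_factory=list)
    entities: list[Entity] = field(default_factory=list)
    attributes: list[Attribute] = field(default_factory=list)

    def entity_by_id(self, eid: str) -> Entity | None:
        for ent in self.entities:
            if ent.id == eid:
                return ent
        return None

    def entities_in_layer(self, layer: str) -> list[Entity]:
        return [e for e in self.entities if e.layer == layer]


# ---------------------------------------------------------------------------
# Text normalization
# ---------------------------------------------------------------------------

#: Same-length character substitutions applied before segmentation.  These are
#: characters that commonly break downstream tokenizers or sequence models:
#: typographic quotes, exotic space characters, soft hyphens and dashes.
DEFAULT_SUBSTITUTIONS: dict[str, str] = {
    " ": " ",  # no-break space
    " ": " ",  # figure space
    " ": " ",  # thin space
    " ": " ",  # hair space
    " ": " ",  # narrow no-break space
    "‘": "'",
    "’": "'",
    "‚": "'",
    "“": '"',
    "”": '"',
    "«": '"',
    "»": '"',
    "­": "-",  # soft hyphen
    "‐": "-",
    "‑": "-",
    "–": "-",  # en dash
    "—": "-",  # em dash
    "−": "-",  # minus sign
}


class ConfigurationError(ValueError):
    """Raised for invalid configuration values (bad tables, schemes, keys)."""


def normalize_text(
    raw: str, substitution_table: dict[str, str] | None = None
) -> str:
    """Apply same-length character substitutions to ``raw``.

    The output has exactly the same length as the input (so raw and
    normalized offsets coincide) and the operation is idempotent.
    """
    table = DEFAULT_SUBSTITUTIONS if substitution_table is None else substitution_table
    for src, dst in table.items():
        if len(src) != 1 or len(dst) != 1:
            raise ConfigurationError(
                f"substitution table must map single characters: {src!r} -> {dst!r}"
            )
    return raw.translate({ord(src): dst for src, dst in table.items()})


# ---------------------------------------------------------------------------
# Segmentation providers
# ---------------------------------------------------------------------------


class TokenizerProvider(Protocol):
    """Contract for an injected tokenizer/lemmatizer.

    ``__call__(text)`` returns a list of :class:`Sentence` whose token
    offsets index into ``text`` (code points, end-exclusive) and whose token
    surfaces equal the corresponding text slices.  Lemma and coarse POS are
    optional per token.
    """

    def __call__(self, text: str) -> list[Sentence]: ...


_TOKEN_RE = re.compile(r"\d+(?:[.,]\d+)?|\w+|[^\w\s]", re.UNICODE)
_SENT_END_RE = re.compile(r"[.!?]+(?:\s+|$)")


class RuleTokenizer:
    """Dependency-free whitespace/punctuation tokenizer and sentence splitter.

    Sentences end at ``. ! ?`` runs followed by whitespace or end-of-text.
    Tokens are number literals (decimal comma or dot), word-character runs,
    or single punctuation marks.  The lemma is the lower-cased surface; no
    POS tags are produced.
    """

    def __call__(self, text: str) -> list[Sentence]:
        sentences: list[Sentence] = []
        pos = 0
        bounds: list[tuple[int, int]] = []
        for m in _SENT_END_RE.finditer(text):
            bounds.append((pos, m.end()))
            pos = m.end()
        if pos < len(text):
            bounds.append((pos, len(text)))
        for s, e in bounds:
            tokens = [
                Token(
                    surface=m.group(),
                    start=s + m.start(),
                    end=s + m.end(),
                    lemma=m.group().lower(),
                )
                for m in _TOKEN_RE.finditer(text[s:e])
            ]
            if not tokens:
                continue
            sentences.append(
                Sentence(start=tokens[0].start, end=tokens[-1].end, tokens=tokens)
            )
        return sentences


class SpacyProvider:
    """Wrapper around a spaCy Spanish pipeline satisfying the provider
    contract.  Imported lazily; requires the optional ``spacy`` dependency
    and an installed Spanish model."""

    def __init__(self, model: str = "es_core_news_sm"):
        import spacy  # deferred import: optional dependency

        self.nlp = spacy.load(model)

    def __call__(self, text: str) -> list[Sentence]:
        doc = self.nlp(text)
        sentences = []
        for sent in doc.sents:
            tokens = [
                Token(
                    surface=t.text,
                    start=t.idx,
                    end=t.idx + len(t.text),
                    lemma=t.lemma_,
                    pos=t.pos_,
                )
                for t in sent
                if not t.is_space
            ]
            if tokens:
                sentences.append(
                    Sentence(start=tokens[0].start, end=tokens[-1].end, tokens=tokens)
                )
        return sentences


def make_document(
    doc_id: str,
    raw_text: str,
    substitution_table: dict[str, str] | None = None,
) -> Document:
    """Create a normalized, unsegmented document."""
    return Document(
        doc_id=doc_id,
        raw_text=raw_text,
        text=normalize_text(raw_text, substitution_table),
    )


def segment(doc: Document, provider: TokenizerProvider | None = None) -> Document:
    """Populate ``doc.sentences`` using the injected provider (in place).

    Raises ``ValueError`` if the provider returns offsets that do not index
    into ``doc.text`` or token surfaces that do not equal their slices.
    """
    provider = provider or RuleTokenizer()
    sentences = provider(doc.text)
    n = len(doc.text)
    for sent in sentences:
        if not (0 <= sent.start < sent.end <= n):
            raise ValueError(f"sentence offsets out of bounds: {sent.start}:{sent.end}")
        for tok in sent.tokens:
            if not (sent.start <= tok.start < tok.end <= sent.end):
                raise ValueError(f"token outside sentence: {tok}")
            if doc.text[tok.start : tok.end] != tok.surface:
                raise ValueError(
                    f"token surface mismatch at {tok.start}:{tok.end}: {tok.surface!r}"
                )
    doc.sentences = sentences
    return doc


def sentence_at(doc: Document, start: int, end: int) -> Sentence | None:
    """Return the sentence containing [start, end), or None."""
    for sent in doc.sentences:
        if sent.start <= start and end <= sent.end:
            return sent
    return None


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_document(doc: Document) -> list[dict]:
    """Check all data-model invariants; return violation records.

    Never raises.  Each record has ``id`` (entity/attribute/sentence id or
    index) and ``rule`` (the invariant broken).
    """
    violations: list[dict] = []

    def bad(obj_id: str, rule: str) -> None:
        violations.append({"id": obj_id, "rule": rule})

    n = len(doc.text)
    if len(doc.text) != len(doc.raw_text):
        bad(doc.doc_id, "normalization changed text length")

    for i, sent in enumerate(doc.sentences):
        sid = f"sentence[{i}]"
        if not (0 <= sent.start < sent.end <= n):
            bad(sid, "sentence offsets out of bounds")
            continue
        prev_end = sent.start
        for j, tok in enumerate(sent.tokens):
            tid = f"{sid}.token[{j}]"
            if not (sent.start <= tok.start < tok.end <= sent.end):
                bad(tid, "token outside sentence span")
            elif tok.start < prev_end:
                bad(tid, "tokens overlap or out of order")
            if 0 <= tok.start < tok.end <= n and doc.text[tok.start : tok.end] != tok.surface:
                bad(tid, "token surface does not equal text slice")
            prev_end = max(prev_end, tok.end)

    ids_seen: set[str] = set()
    for ent in doc.entities:
        if ent.id in ids_seen:
            bad(ent.id, "duplicate entity id")
        ids_seen.add(ent.id)
        if ent.label not in ENTITY_LABELS:
            bad(ent.id, f"label not in vocabulary: {ent.label}")
            continue
        if not (0 <= ent.start < ent.end <= n):
            bad(ent.id, "entity offsets out of bounds")
            continue
        if doc.text[ent.start : ent.end] != ent.surface:
            bad(ent.id, "entity surface does not equal text slice")
        if ent.source not in ENTITY_SOURCES:
            bad(ent.id, f"unknown entity source: {ent.source}")
        if ent.score is not None and not (0.0 <= ent.score <= 1.0):
            bad(ent.id, "score outside [0, 1]")

    # partial overlap within a layer (identical spans allowed in umls layer
    # for multi-group terms)
    by_layer: dict[str, list[Entity]] = {}
    for ent in doc.entities:
        if ent.label in ENTITY_LABELS:
            by_layer.setdefault(ent.layer, []).append(ent)
    for layer, ents in by_layer.items():
        ents = sorted(ents, key=lambda e: (e.start, e.end))
        for a, b in zip(ents, ents[1:]):
            if a.overlaps(b) and not (
                layer == "umls" and (a.start, a.end) == (b.start, b.end)
            ):
                bad(b.id, f"entities overlap within layer {layer}: {a.id}/{b.id}")

    entity_ids = {e.id for e in doc.entities}
    seen_attr: set[tuple[str, str]] = set()
    for attr in doc.attributes:
        if attr.type not in ATTRIBUTE_TYPES:
            bad(attr.id, f"attribute type not in vocabulary: {attr.type}")
        if attr.target not in entity_ids:
            bad(attr.id, f"attribute targets missing entity: {attr.target}")
        key = (attr.target, attr.type)
        if key in seen_attr:
            bad(attr.id, f"duplicate attribute type {attr.type} on {attr.target}")
        seen_attr.add(key)

    return violations


# ---------------------------------------------------------------------------
# Small shared helpers
# ---------------------------------------------------------------------------

_ACCENT_MAP = str.maketrans(
    "áàäâéèëêíìïîóòöôúùüûÁÀÄÂÉÈËÊÍÌÏÎÓÒÖÔÚÙÜÛ",
    "aaaaeeeeiiiioooouuuuAAAAEEEEIIIIOOOOUUUU",
)


def strip_accents(s: str) -> str:
    """Remove accents from Spanish vowels; ñ/Ñ are preserved (they are
    distinct letters, not accented variants)."""
    return s.translate(_ACCENT_MAP)


def next_id(prefix: str, existing: Iterable[str]) -> str:
    """Smallest unused ``{prefix}{n}`` identifier (n starting at 1)."""
    taken = set(existing)
    n = 1
    while f"{prefix}{n}" in taken:
        n += 1
    return f"{prefix}{n}"
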