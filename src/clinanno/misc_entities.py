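"""Miscellaneous clinical entities.

Result_or_Value (comparator + number + optional unit, e.g. "< 3 UNL") and
Quantifier_or_Qualifier (quantity phrases like "al menos 4" and a starter
list of severity/laterality/extent adjectives) are pattern-driven; CONC,
Food_or_Drink and Observation_or_Finding are recognized through the lexicon
matcher restricted to those semantic groups.
"""

from __future__ import annotations

import re

from .core import Document, Entity, ENTITY_LABELS, strip_accents
from .lexicon import Lexicon, match_entities
from .numbers import NUM
from .resources import load_term_set

MISC_LEXICON_GROUPS = frozenset({"CONC", "Food_or_Drink", "Observation_or_Finding"})

_RESULT_RE = re.compile(
    rf"(?:<=|>=|≤|≥|<|>|=)\s*(?i:{NUM})\s*(?:%|‰|(?<=\s)[A-Za-zµμ][\w%²/]*)?(?!\w)"
)

_QUANT_RE = re.compile(
    rf"(?<!\w)(?:al\s+menos|como\s+m[ií]nimo|como\s+m[áa]ximo|un\s+m[ií]nimo\s+de"
    rf"|un\s+m[áa]ximo\s+de)\s+{NUM}(?!\w)",
    re.IGNORECASE,
)

COMPARATORS = ("<", ">", "≤", "≥", "=")


def _span_entities(doc: Document, rx: re.Pattern, label: str) -> list[Entity]:
    out = []
    for sent in doc.sentences:
        text = doc.text[sent.start : sent.end]
        for m in rx.finditer(text):
            start, end = sent.start + m.start(), sent.start + m.end()
            out.append(
                Entity(
                    id="",
                    label=label,
                    start=start,
                    end=end,
                    surface=doc.text[start:end].strip(),
                    source="rules",
                )
            )
    # strip() above can only trim a trailing gap captured before an absent
    # unit; re-anchor spans on the stripped surface
    for ent in out:
        if doc.text[ent.start : ent.end] != ent.surface:
            ent.end = ent.start + len(ent.surface)
    return out


def tag_result_value(doc: Document) -> list[Entity]:
    """Tag Result_or_Value spans: comparator through number and optional
    unit.  A bare number never matches."""
    return _span_entities(doc, _RESULT_RE, "Result_or_Value")


def tag_quantifier(
    doc: Document, qualifier_terms: set[str] | None = None
) -> list[Entity]:
    """Tag Quantifier_or_Qualifier: quantity phrases ("al menos 4") and
    listed qualifier adjectives ("grave")."""
    if qualifier_terms is None:
        qualifier_terms = load_qualifier_terms()
    out = _span_entities(doc, _QUANT_RE, "Quantifier_or_Qualifier")
    for sent in doc.sentences:
        for tok in sent.tokens:
            if strip_accents(tok.surface.lower()) in qualifier_terms:
                if any(e.start <= tok.start and tok.end <= e.end for e in out):
                    continue
                out.append(
                    Entity(
                        id="",
                        label="Quantifier_or_Qualifier",
                        start=tok.start,
                        end=tok.end,
                        surface=tok.surface,
                        source="rules",
                    )
                )
    return sorted(out, key=lambda e: (e.start, e.end))


def load_qualifier_terms(path=None) -> set[str]:
    if path is None:
        terms = load_term_set("qualifiers.txt")
    else:
        terms = set()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    terms.add(line.lower())
    return {strip_accents(t) for t in terms}


def tag_misc_lexicon(doc: Document, lexicon: Lexicon) -> list[Entity]:
    """CONC, Food_or_Drink and Observation_or_Finding entities via the
    dictionary matcher, restricted to those groups."""
    excluded = frozenset(ENTITY_LABELS - MISC_LEXICON_GROUPS)
    return match_entities(doc, lexicon, excluded_groups=excluded, source="dictionary")


def tag_misc(doc: Document, lexicon: Lexicon | None = None,
             qualifier_terms: set[str] | None = None) -> list[Entity]:
    """All misc-layer entities, non-overlapping (lexicon entities win over
    pattern spans they overlap, result/value wins over bare qualifiers)."""
    ents = tag_result_value(doc)
    lex_ents = tag_misc_lexicon(doc, lexicon) if lexicon is not None else []
    kept: list[Entity] = list(lex_ents)
    for ent in ents + tag_quantifier(doc, qualifier_terms):
        if not any(ent.overlaps(k) for k in kept):
            kept.append(ent)
    return sorted(kept, key=lambda e: (e.start, e.end))
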