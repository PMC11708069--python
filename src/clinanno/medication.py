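"""Rule-based recognition of medication-related entities: Dose (dose,
concentration or strength, merged into one class), Route (mode of
administration) and Form (dosage form).

Term lists follow the structure of the Spanish Medicines Agency Nomenclátor
vocabularies and are shipped as editable data files.  A Dose is a number
(digits with Spanish decimal comma or dot, a number word, or a simple
range) followed by a unit, optionally with a per-denominator (mg/kg,
UI/m2).  Routes and forms are list lookups that are robust to case and
accent variation; route abbreviations (IV, SC, ...) are matched
case-sensitively, and a preceding "vía" is absorbed into the Route span.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .core import Document, Entity, strip_accents
from .numbers import NUM_OR_RANGE
from .resources import expand_inflections, iter_data_lines

def _fold(s: str) -> str:
    return strip_accents(s.lower())


@dataclass
class MedTermLists:
    routes: set[str] = field(default_factory=set)  # folded forms
    route_abbrevs: set[str] = field(default_factory=set)  # raw, case-sensitive
    forms: set[str] = field(default_factory=set)  # folded forms
    units: list[str] = field(default_factory=list)  # case-sensitive
    denominators: list[str] = field(default_factory=list)


def load_med_term_lists(
    routes_path=None, forms_path=None, units_path=None
) -> MedTermLists:
    lists = MedTermLists()

    def lines(name, path):
        if path is None:
            yield from iter_data_lines(name)
        else:
            with open(path, encoding="utf-8") as fh:
                for l in fh:
                    l = l.rstrip("\n")
                    if l.strip() and not l.lstrip().startswith("#"):
                        yield l

    for line in lines("routes.txt", routes_path):
        cols = line.split("\t")
        if len(cols) > 1 and cols[1].strip() == "abbrev":
            lists.route_abbrevs.add(cols[0].strip())
        else:
            term = cols[0].strip().lower()
            lists.routes |= {_fold(v) for v in expand_inflections(term, gender=True)}
    for line in lines("forms.txt", forms_path):
        term = line.split("\t")[0].strip().lower()
        lists.forms |= {_fold(v) for v in expand_inflections(term)}
    for line in lines("dose_units.txt", units_path):
        term = line.split("\t")[0].strip()
        if term.startswith("/"):
            lists.denominators.append(term[1:])
        else:
            lists.units.append(term)
    if not (lists.routes and lists.forms and lists.units):
        raise ValueError("medication term lists must be non-empty")
    return lists


def _dose_regex(lists: MedTermLists) -> re.Pattern:
    unit_alt = "|".join(re.escape(u) for u in sorted(lists.units, key=len, reverse=True))
    den_alt = "|".join(
        re.escape(d) for d in sorted(set(lists.denominators), key=len, reverse=True)
    )
    return re.compile(
        rf"(?<![\w.,])(?i:{NUM_OR_RANGE})\s*(?:{unit_alt})(?:\s*/\s*(?:{den_alt}))?(?![\w/])"
    )


def tag_dose(doc: Document, lists: MedTermLists | None = None) -> list[Entity]:
    """Tag Dose entities; the span covers the number through the (compound)
    unit.  A bare unit with no preceding number never matches."""
    lists = lists or load_med_term_lists()
    rx = _dose_regex(lists)
    out = []
    for sent in doc.sentences:
        text = doc.text[sent.start : sent.end]
        for m in rx.finditer(text):
            start, end = sent.start + m.start(), sent.start + m.end()
            out.append(
                Entity(
                    id="",
                    label="Dose",
                    start=start,
                    end=end,
                    surface=doc.text[start:end],
                    source="rules",
                )
            )
    return out


_VIA = {"via"}  # folded "vía"


def tag_route(doc: Document, lists: MedTermLists | None = None) -> list[Entity]:
    """Tag Route entities by list lookup (folded), with case-sensitive
    abbreviations and "vía X" prefix absorption."""
    lists = lists or load_med_term_lists()
    out = []
    for sent in doc.sentences:
        for i, tok in enumerate(sent.tokens):
            if tok.surface in lists.route_abbrevs or _fold(tok.surface) in lists.routes:
                start = tok.start
                if i > 0 and _fold(sent.tokens[i - 1].surface) in _VIA:
                    start = sent.tokens[i - 1].start
                out.append(
                    Entity(
                        id="",
                        label="Route",
                        start=start,
                        end=tok.end,
                        surface=doc.text[start : tok.end],
                        source="rules",
                    )
                )
    return out


def tag_form(doc: Document, lists: MedTermLists | None = None) -> list[Entity]:
    """Tag Form (dosage form) entities by list lookup with inflectional
    (plural) variants."""
    lists = lists or load_med_term_lists()
    out = []
    for sent in doc.sentences:
        for tok in sent.tokens:
            if _fold(tok.surface) in lists.forms:
                out.append(
                    Entity(
                        id="",
                        label="Form",
                        start=tok.start,
                        end=tok.end,
                        surface=tok.surface,
                        source="rules",
                    )
                )
    return out


def tag_medication(doc: Document, lists: MedTermLists | None = None) -> list[Entity]:
    """All medication-layer entities (Dose, Route, Form), non-overlapping:
    Dose spans win over Route/Form tokens they cover (a unit word is not a
    route)."""
    lists = lists or load_med_term_lists()
    doses = tag_dose(doc, lists)
    others = tag_route(doc, lists) + tag_form(doc, lists)
    kept = list(doses)
    for ent in others:
        if not any(ent.overlaps(d) for d in doses):
            kept.append(ent)
    return sorted(kept, key=lambda e: (e.start, e.end))
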