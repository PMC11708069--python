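"""Dictionary-based entity recognition and concept normalization.

The lexicon follows the structure of Spanish medical lexicons that record a
lemma, its surface variants, one or more UMLS semantic groups and the
normalization codes (UMLS CUIs, SNOMED CT).  Recognition is greedy
left-to-right longest match over token n-grams within each sentence, first
on surface forms, then on lemmas.  Accent folding is on by default
(clinical Spanish is inconsistent about accents) but entries flagged as
abbreviations are matched case-sensitively and unfolded, so that acronyms
like "IV" do not collide with the preposition-free word "iv".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .core import (
    ConfigurationError,
    Document,
    Entity,
    ENTITY_LABELS,
    strip_accents,
)

_CUI_RE = re.compile(r"^C\d{7}$")

LEXICON_COLUMNS = ["lemma", "variants", "groups", "cuis", "snomed", "is_abbrev"]


class LexiconFormatError(ValueError):
    """Malformed lexicon file; message names the offending line number."""


@dataclass
class LexiconEntry:
    lemma: str
    variants: list[str]
    groups: list[str]
    cuis: list[str] = field(default_factory=list)
    snomed: list[str] = field(default_factory=list)
    is_abbrev: bool = False


@dataclass
class FoldConfig:
    accent_fold: bool = True


@dataclass
class Lexicon:
    entries: list[LexiconEntry] = field(default_factory=list)
    #: folded variant key (space-joined folded tokens) -> entry indices
    index: dict[str, list[int]] = field(default_factory=dict)
    #: case-sensitive, unfolded key -> entry indices (abbreviation entries)
    abbrev_index: dict[str, list[int]] = field(default_factory=dict)
    #: maximum token length of any indexed variant
    max_len: int = 0
    fold_config: FoldConfig = field(default_factory=FoldConfig)


def fold(form: str, config: FoldConfig | None = None) -> str:
    """Lookup key for a surface form: lower-cased, accents stripped when
    ``config.accent_fold`` (abbreviation entries bypass this and are matched
    on the raw form)."""
    config = config or FoldConfig()
    key = form.lower()
    if config.accent_fold:
        key = strip_accents(key)
    return key


def _key_tokens(form: str) -> list[str]:
    return form.split()


def _variant_key(form: str, config: FoldConfig) -> str:
    return " ".join(fold(t, config) for t in _key_tokens(form))


def _parse_multi(cell: str) -> list[str]:
    return [v.strip() for v in cell.split("|") if v.strip()] if cell.strip() else []


def parse_lexicon(text: str, fold_config: FoldConfig | None = None) -> Lexicon:
    """Parse lexicon TSV content (see :func:`load_lexicon`)."""
    fold_config = fold_config or FoldConfig()
    lines = text.splitlines()
    if not lines:
        raise LexiconFormatError("line 1: empty lexicon file")
    header = lines[0].rstrip("\n").split("\t")
    if [h.strip() for h in header] != LEXICON_COLUMNS:
        raise LexiconFormatError(
            f"line 1: expected columns {LEXICON_COLUMNS}, got {header}"
        )

    # merge duplicate (form, group) rows by (lemma, sorted groups, abbrev)
    merged: dict[tuple, LexiconEntry] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.rstrip("\n").split("\t")
        if len(cells) != len(LEXICON_COLUMNS):
            raise LexiconFormatError(
                f"line {lineno}: expected {len(LEXICON_COLUMNS)} columns, got {len(cells)}"
            )
        lemma, variants_c, groups_c, cuis_c, snomed_c, abbrev_c = cells
        variants = _parse_multi(variants_c)
        groups = _parse_multi(groups_c)
        cuis = _parse_multi(cuis_c)
        snomed = _parse_multi(snomed_c)
        if not variants:
            raise LexiconFormatError(f"line {lineno}: entry has no variants")
        if not groups:
            raise LexiconFormatError(f"line {lineno}: entry has no semantic groups")
        for g in groups:
            if g not in ENTITY_LABELS:
                raise LexiconFormatError(f"line {lineno}: unknown group {g!r}")
        for cui in cuis:
            if not _CUI_RE.match(cui):
                raise LexiconFormatError(f"line {lineno}: malformed CUI {cui!r}")
        is_abbrev = abbrev_c.strip() in {"1", "true", "True", "yes"}
        key = (lemma, tuple(sorted(groups)), is_abbrev)
        if key in merged:
            entry = merged[key]
            entry.variants += [v for v in variants if v not in entry.variants]
            entry.cuis += [c for c in cuis if c not in entry.cuis]
            entry.snomed += [c for c in snomed if c not in entry.snomed]
        else:
            merged[key] = LexiconEntry(
                lemma=lemma,
                variants=list(variants),
                groups=list(groups),
                cuis=list(cuis),
                snomed=list(snomed),
                is_abbrev=is_abbrev,
            )

    lex = Lexicon(entries=list(merged.values()), fold_config=fold_config)
    _build_index(lex)
    return lex


def _build_index(lex: Lexicon) -> None:
    lex.index.clear()
    lex.abbrev_index.clear()
    lex.max_len = 0
    for i, entry in enumerate(lex.entries):
        forms = entry.variants + [entry.lemma]
        for form in forms:
            ntok = len(_key_tokens(form))
            lex.max_len = max(lex.max_len, ntok)
            if entry.is_abbrev:
                lex.abbrev_index.setdefault(" ".join(_key_tokens(form)), [])
                if i not in lex.abbrev_index[" ".join(_key_tokens(form))]:
                    lex.abbrev_index[" ".join(_key_tokens(form))].append(i)
            else:
                key = _variant_key(form, lex.fold_config)
                lex.index.setdefault(key, [])
                if i not in lex.index[key]:
                    lex.index[key].append(i)


def load_lexicon(path, fold_config: FoldConfig | None = None) -> Lexicon:
    """Load a lexicon from a UTF-8 TSV file.

    Columns: ``lemma  variants  groups  cuis  snomed  is_abbrev`` with ``|``
    separating multi-values and empty cells meaning "none".
    """
    with open(path, encoding="utf-8") as fh:
        return parse_lexicon(fh.read(), fold_config)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def _lookup(lex: Lexicon, surfaces: list[str], lemmas: list[str]) -> list[int]:
    """Entry indices matching a token window.

    Tried in evidence order: abbreviation (case-sensitive raw surface),
    folded surface, folded lemma.  A surface match and a lemma match of the
    same window length both land here; surface evidence is returned first so
    callers can prefer it.
    """
    raw = " ".join(surfaces)
    found: list[int] = []
    for idx in lex.abbrev_index.get(raw, []):
        found.append(idx)
    skey = " ".join(fold(s, lex.fold_config) for s in surfaces)
    for idx in lex.index.get(skey, []):
        if idx not in found:
            found.append(idx)
    lkey = " ".join(fold(l, lex.fold_config) for l in lemmas)
    if lkey != skey:
        for idx in lex.index.get(lkey, []):
            if idx not in found:
                found.append(idx)
    return found


def match_entities(
    doc: Document,
    lexicon: Lexicon,
    excluded_groups: set[str] | frozenset[str] = frozenset(),
    source: str = "dictionary",
) -> list[Entity]:
    """Greedy left-to-right longest-match dictionary NER.

    Matching is sentence-bounded and runs over token n-grams (n up to the
    longest indexed variant), trying the surface sequence before the lemma
    sequence.  A matched span emits one entity per semantic group of the
    matching entries; ``excluded_groups`` filters the *emitted* entities
    only, so excluding one group never changes the spans found for others.
    Entity ids are left empty for the caller to assign.
    """
    if not doc.sentences and doc.text.strip():
        raise ValueError("document must be segmented before matching")
    out: list[Entity] = []
    for sent in doc.sentences:
        toks = sent.tokens
        i = 0
        while i < len(toks):
            hit: list[int] | None = None
            hit_n = 0
            for n in range(min(lexicon.max_len, len(toks) - i), 0, -1):
                window = toks[i : i + n]
                surfaces = [t.surface for t in window]
                lemmas = [t.lemma or t.surface for t in window]
                found = _lookup(lexicon, surfaces, lemmas)
                if found:
                    hit = found
                    hit_n = n
                    break
            if hit is None:
                i += 1
                continue
            start = toks[i].start
            end = toks[i + hit_n - 1].end
            surface = doc.text[start:end]
            groups_seen: list[str] = []
            for idx in hit:
                entry = lexicon.entries[idx]
                for g in entry.groups:
                    if g in excluded_groups or g in groups_seen:
                        continue
                    groups_seen.append(g)
                    out.append(
                        Entity(
                            id="",
                            label=g,
                            start=start,
                            end=end,
                            surface=surface,
                            codes=[("UMLS", c) for c in entry.cuis]
                            + [("SNOMEDCT", c) for c in entry.snomed],
                            source=source,
                        )
                    )
            i += hit_n
    return out


def normalize_entity(entity: Entity, lexicon: Lexicon, scheme: str) -> Entity:
    """Restrict/refresh an entity's codes to one normalization scheme.

    Codes are looked up from the lexicon by the entity's surface form
    (entities produced by :func:`match_entities` or span-identical to a
    lexicon variant); an unknown surface leaves the entity unchanged except
    for an empty code list.
    """
    if scheme not in {"UMLS", "SNOMEDCT"}:
        raise ConfigurationError(f"unknown normalization scheme: {scheme!r}")
    surfaces = entity.surface.split()
    indices = _lookup(lexicon, surfaces, [s.lower() for s in surfaces])
    codes: list[tuple[str, str]] = []
    for idx in indices:
        entry = lexicon.entries[idx]
        if entity.label not in entry.groups:
            continue
        values = entry.cuis if scheme == "UMLS" else entry.snomed
        for v in values:
            if (scheme, v) not in codes:
                codes.append((scheme, v))
    entity.codes = codes
    return entity
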