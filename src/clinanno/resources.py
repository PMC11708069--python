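"""Access to the packaged rule tables and term lists under ``clinanno/data``.

All data files are editable UTF-8 text; lines starting with ``#`` and blank
lines are comments.  Term lists are canonical lowercase singular forms;
:func:`expand_inflections` derives Spanish plural (and for ``-o`` adjectives,
feminine) variants at load time.
"""

from __future__ import annotations

from importlib import resources as _ilres

_VOWELS = "aeiouáéíóú"


def data_text(name: str) -> str:
    return (_ilres.files("clinanno") / "data" / name).read_text(encoding="utf-8")


def iter_data_lines(name: str):
    for line in data_text(name).splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield line


def pluralize_es(term: str) -> str:
    """Regular Spanish plural: -ón → -ones, vowel → +s, consonant → +es."""
    if term.endswith("ón"):
        return term[:-2] + "ones"
    if term.endswith("ión"):  # pragma: no cover - covered by -ón branch
        return term[:-3] + "iones"
    if term and term[-1] in _VOWELS:
        return term + "s"
    return term + "es"


def expand_inflections(term: str, gender: bool = False) -> set[str]:
    """Inflectional variants of a canonical term: plural, and when
    ``gender`` and the term ends in ``-o``, the feminine forms too."""
    bases = {term}
    if gender and term.endswith("o"):
        bases.add(term[:-1] + "a")
    out = set()
    for b in bases:
        out.add(b)
        out.add(pluralize_es(b))
    return out


def load_term_set(name: str, gender: bool = False) -> set[str]:
    """Load a one-term-per-line list, expanded with inflectional variants.
    Entries with a second tab-separated column are returned verbatim by
    callers that handle flags; this helper keeps only the first column."""
    terms: set[str] = set()
    for line in iter_data_lines(name):
        term = line.split("\t")[0].strip().lower()
        terms |= expand_inflections(term, gender=gender)
    return terms
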