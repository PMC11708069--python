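"""Rule-based recognition of temporal entities (Date, Duration, Frequency,
Time, Age).

The rules are regular expressions over sentence text, in the spirit of the
HeidelTime resources for Spanish, shipped as an editable data file
(``data/temporal_rules.tsv``: pattern, class, priority).  Spans follow the
TimeML classes plus Age; there is no value normalization — only span and
class are annotated.

Age disambiguation: a "N años" match is kept as Age only when an
age-denoting trigger word ("edad", "mayores", "menores", ...) occurs within
a ±4-token window; otherwise it demotes to Duration.  "pre-"/"post-"
prefixed expressions (e.g. "posoperatorio") are Date by default and Time
when the head is a time-of-day word; they are never merged into a separate
class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .core import Document, Entity, Sentence, strip_accents
from .numbers import DIGITS, NUM
from .resources import iter_data_lines

TUNIT = r"(?:segundos?|minutos?|horas?|días?|dias?|semanas?|meses|mes|años?)"
MONTH = (
    r"(?:enero|febrero|marzo|abril|mayo|junio|julio|agosto|septiembre"
    r"|setiembre|octubre|noviembre|diciembre)"
)

TEMPORAL_CLASSES = {"Date", "Duration", "Frequency", "Time", "Age"}

#: Priority a demoted Age match falls back to (the Duration rule priority).
DURATION_PRIORITY = 20

#: Tokens that license an Age reading of "N años" in a ±4-token window.
AGE_TRIGGERS = {"edad", "edades", "mayores", "menores", "mayor", "menor"}

AGE_WINDOW = 4


@dataclass
class TemporalRule:
    pattern: re.Pattern
    klass: str
    priority: int
    raw: str = ""


@dataclass
class Candidate:
    """A candidate span before overlap resolution."""

    start: int
    end: int
    klass: str
    priority: int


def _compile(raw: str) -> re.Pattern:
    expanded = (
        raw.replace("{NUM}", NUM)
        .replace("{DIGITS}", DIGITS)
        .replace("{TUNIT}", TUNIT)
        .replace("{MONTH}", MONTH)
    )
    return re.compile(rf"(?<!\w)(?:{expanded})(?!\w)", re.IGNORECASE)


def load_temporal_rules(path=None) -> list[TemporalRule]:
    """Load rules from ``path`` or the packaged default table."""
    if path is None:
        lines = list(iter_data_lines("temporal_rules.tsv"))
    else:
        with open(path, encoding="utf-8") as fh:
            lines = [
                l.rstrip("\n")
                for l in fh
                if l.strip() and not l.lstrip().startswith("#")
            ]
    rules = []
    for line in lines:
        pattern, klass, priority = line.split("\t")
        if klass not in TEMPORAL_CLASSES:
            raise ValueError(f"unknown temporal class {klass!r}")
        rules.append(TemporalRule(_compile(pattern), klass, int(priority), pattern))
    return rules


def _has_age_trigger(sent: Sentence, start: int, end: int) -> bool:
    idx = [i for i, t in enumerate(sent.tokens) if t.start < end and start < t.end]
    if not idx:
        return False
    lo, hi = max(0, idx[0] - AGE_WINDOW), min(len(sent.tokens), idx[-1] + 1 + AGE_WINDOW)
    for tok in sent.tokens[lo:hi]:
        if strip_accents(tok.surface.lower()) in AGE_TRIGGERS:
            return True
    return False


def resolve_overlaps(candidates: list[Candidate]) -> list[Candidate]:
    """Keep a non-overlapping subset: higher priority first, then longer
    span, then smaller start.  Identical (span, class) duplicates collapse."""
    kept: list[Candidate] = []
    for cand in sorted(
        candidates, key=lambda c: (-c.priority, -(c.end - c.start), c.start)
    ):
        if any(c.start < cand.end and cand.start < c.end for c in kept):
            continue
        kept.append(cand)
    return sorted(kept, key=lambda c: c.start)


def tag_temporal(
    doc: Document, rules: list[TemporalRule] | None = None
) -> list[Entity]:
    """Tag temporal entities in a segmented document.

    Deterministic: candidates are collected per sentence, Age candidates
    without an age trigger demote to Duration, and
    :func:`resolve_overlaps` selects the surviving spans.
    """
    if rules is None:
        rules = load_temporal_rules()
    out: list[Entity] = []
    for sent in doc.sentences:
        text = doc.text[sent.start : sent.end]
        candidates: list[Candidate] = []
        for rule in rules:
            for m in rule.pattern.finditer(text):
                start, end = sent.start + m.start(), sent.start + m.end()
                klass, prio = rule.klass, rule.priority
                if klass == "Age" and not _has_age_trigger(sent, start, end):
                    klass, prio = "Duration", DURATION_PRIORITY
                candidates.append(Candidate(start, end, klass, prio))
        for cand in resolve_overlaps(candidates):
            out.append(
                Entity(
                    id="",
                    label=cand.klass,
                    start=cand.start,
                    end=cand.end,
                    surface=doc.text[cand.start : cand.end],
                    source="rules",
                )
            )
    return out
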