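"""Packaged Spanish number grammar.

A regex alternation covering digit literals (decimal comma or dot, simple
ranges) and Spanish number words up to ninety-nine, including the fused
forms (dieciséis, veintiuno) and "y"-compounds (treinta y dos).  Used by the
temporal, medication and miscellaneous-entity taggers, which need to match
expressions like "dos horas" or "al menos 4".
"""

from __future__ import annotations

import re

_UNITS = (
    "un|uno|una|dos|tres|cuatro|cinco|seis|siete|ocho|nueve"
)
_TEENS = (
    "diez|once|doce|trece|catorce|quince|dieciséis|dieciseis|diecisiete"
    "|dieciocho|diecinueve"
)
_TWENTIES = (
    "veinte|veintiuno|veintiún|veintiun|veintiuna|veintidós|veintidos"
    "|veintitrés|veintitres|veinticuatro|veinticinco|veintiséis|veintiseis"
    "|veintisiete|veintiocho|veintinueve"
)
_TENS = "treinta|cuarenta|cincuenta|sesenta|setenta|ochenta|noventa"

#: Word-form numbers: tens optionally compounded with "y <unit>".
NUMBER_WORD = rf"(?:(?:{_TENS})(?:\s+y\s+(?:{_UNITS}))?|{_TWENTIES}|{_TEENS}|{_UNITS})"

#: Digit literal with optional decimal part (Spanish comma or dot).
DIGITS = r"\d+(?:[.,]\d+)?"

#: Any number: digits or a number word.
NUM = rf"(?:{DIGITS}|{NUMBER_WORD})"

#: Number or digit range ("10-20", "10 - 20").
NUM_OR_RANGE = rf"(?:{DIGITS}\s*-\s*{DIGITS}|{NUM})"

NUM_RE = re.compile(rf"^{NUM}$", re.IGNORECASE)


def is_number_token(tok: str) -> bool:
    return bool(NUM_RE.match(tok))
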