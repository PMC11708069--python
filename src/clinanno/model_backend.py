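"""Pluggable token-classification backend: adapter contract, BIO-to-span
decoding with repair, and the hybrid merge of model and dictionary output.

An adapter receives sentences as token lists and returns exactly one BIO
label and one confidence per input token; any subword tokenization a real
model performs is the adapter's private business (first-subword labeling
convention).  All shipped tests run on the deterministic mock adapter; real
pretrained-model adapters plug in behind the same contract.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Protocol

from .core import Entity, Token

_BIO_RE = re.compile(r"^(?:O|[BI]-\S+)$")


class ModelAdapter(Protocol):
    def predict(
        self, sentences: list[list[str]]
    ) -> list[tuple[list[str], list[float]]]:
        """Per sentence: (BIO labels, confidences), one per input token."""
        ...


@dataclass
class MergePolicy:
    precedence: str = "model_first"  # or "dictionary_first"
    dictionary_only_groups: frozenset = frozenset({"ACTI"})
    enrich_codes: bool = True

    def __post_init__(self):
        if self.precedence not in {"model_first", "dictionary_first"}:
            raise ValueError(f"unknown precedence {self.precedence!r}")


def bio_to_spans(
    text: str,
    tokens: list[Token],
    labels: list[str],
    scores: list[float] | None = None,
    source: str = "model",
) -> list[Entity]:
    """Decode BIO labels over tokens into entities.

    Invalid transitions are repaired: ``I-X`` after ``O``, or after a run of
    a different type, is treated as ``B-X``.  Raises ``ValueError`` on a
    length mismatch or a malformed label string.
    """
    if len(tokens) != len(labels):
        raise ValueError(
            f"adapter contract violated: {len(tokens)} tokens vs {len(labels)} labels"
        )
    for lab in labels:
        if not _BIO_RE.match(lab):
            raise ValueError(f"malformed BIO label {lab!r}")
    entities: list[Entity] = []
    run_type: str | None = None
    run_start = 0
    run_scores: list[float] = []

    def close(end_idx: int) -> None:
        nonlocal run_type
        if run_type is None:
            return
        start = tokens[run_start].start
        end = tokens[end_idx].end
        entities.append(
            Entity(
                id="",
                label=run_type,
                start=start,
                end=end,
                surface=text[start:end],
                source=source,
                score=(min(run_scores) if run_scores else None),
            )
        )
        run_type = None

    for i, lab in enumerate(labels):
        score = scores[i] if scores is not None else None
        if lab == "O":
            close(i - 1)
            continue
        prefix, etype = lab.split("-", 1)
        if prefix == "B" or run_type != etype:  # repair: I-X after O / B-Y
            close(i - 1)
            run_type = etype
            run_start = i
            run_scores = []
        if score is not None:
            run_scores.append(score)
    close(len(labels) - 1)
    return entities


def merge_hybrid(
    model_entities: list[Entity],
    dict_entities: list[Entity],
    policy: MergePolicy | None = None,
) -> list[Entity]:
    """Merge model and dictionary entities from the same layer.

    Under ``model_first``: span-identical same-label pairs merge into one
    entity carrying the dictionary codes (when ``enrich_codes``); on span
    conflicts the model entity is kept; dictionary entities in
    ``dictionary_only_groups`` are always retained, other non-overlapping
    dictionary entities are added.  ``dictionary_first`` mirrors the roles.
    """
    policy = policy or MergePolicy()
    if policy.precedence == "model_first":
        primary, secondary = model_entities, dict_entities
    else:
        primary, secondary = dict_entities, model_entities

    kept: list[Entity] = []
    for ent in primary:
        kept.append(ent)
    for ent in secondary:
        twin = next(
            (
                k
                for k in kept
                if (k.start, k.end, k.label) == (ent.start, ent.end, ent.label)
            ),
            None,
        )
        if twin is not None:
            if policy.enrich_codes and not twin.codes:
                twin.codes = list(ent.codes)
            continue
        if ent.label in policy.dictionary_only_groups and ent.source == "dictionary":
            kept.append(ent)
            continue
        if not any(ent.overlaps(k) for k in kept):
            kept.append(ent)
    return sorted(kept, key=lambda e: (e.start, e.end, e.label))


# ---------------------------------------------------------------------------
# Mock adapter
# ---------------------------------------------------------------------------


@dataclass
class _MockAdapter:
    lookup: dict[tuple[str, ...], tuple[str, ...]] = field(default_factory=dict)

    def predict(self, sentences):
        out = []
        max_len = max((len(k) for k in self.lookup), default=1)
        for toks in sentences:
            labels = ["O"] * len(toks)
            i = 0
            while i < len(toks):
                hit = None
                for n in range(min(max_len, len(toks) - i), 0, -1):
                    key = tuple(toks[i : i + n])
                    if key in self.lookup:
                        hit = self.lookup[key]
                        break
                if hit is None:
                    i += 1
                    continue
                for j, lab in enumerate(hit):
                    labels[i + j] = lab
                i += len(hit)
            out.append((labels, [1.0] * len(toks)))
        return out


def make_mock_adapter(
    lookup: dict[tuple[str, ...] | str, tuple[str, ...] | str]
) -> ModelAdapter:
    """Deterministic adapter for tests: maps token sequences to BIO label
    sequences; unknown tokens get O with score 1.0.  Keys/values may be
    space-separated strings for convenience."""
    normalized: dict[tuple[str, ...], tuple[str, ...]] = {}
    for key, val in lookup.items():
        ktoks = tuple(key.split()) if isinstance(key, str) else tuple(key)
        vlabs = tuple(val.split()) if isinstance(val, str) else tuple(val)
        if len(ktoks) != len(vlabs):
            raise ValueError(f"lookup length mismatch for {ktoks}")
        for lab in vlabs:
            if not _BIO_RE.match(lab):
                raise ValueError(f"malformed BIO label {lab!r} in lookup")
        normalized[ktoks] = vlabs
    return _MockAdapter(normalized)


def load_mock_lookup(path) -> dict[tuple[str, ...], tuple[str, ...]]:
    """Mock-adapter lookup table from TSV: token sequence <TAB> label
    sequence (both space-separated)."""
    lookup = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            toks, labs = line.split("\t")
            lookup[tuple(toks.split())] = tuple(labs.split())
    return lookup
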