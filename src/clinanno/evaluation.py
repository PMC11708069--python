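"""Entity-level evaluation: strict and relaxed matching, micro-averaged
precision/recall/F1, pairwise-F1 inter-annotator agreement, and corpus
statistics.

Strict match counts a true positive only when (start, end, label) agree
exactly; relaxed match requires the same label and at least one character
of overlap, pairing gold and predicted entities one-to-one greedily by
descending overlap length.  P = TP/(TP+FP), R = TP/(TP+FN),
F1 = 2PR/(P+R); all three are 0 by convention when a denominator is 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .core import Document, Entity

logger = logging.getLogger("clinanno")


@dataclass
class Counts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "Counts") -> "Counts":
        return Counts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


#: per-label mapping label -> Counts
MatchCounts = dict


@dataclass
class Metrics:
    p: float
    r: float
    f1: float


def _key_strict(ent: Entity) -> tuple:
    return (ent.start, ent.end, ent.label)


def compare_strict(gold: list[Entity], pred: list[Entity]) -> MatchCounts:
    """Exact-match counts per label: TP iff (start, end, label) identical
    (multiset semantics)."""
    counts: MatchCounts = {}
    labels = {e.label for e in gold} | {e.label for e in pred}
    for label in labels:
        g = [_key_strict(e) for e in gold if e.label == label]
        p = [_key_strict(e) for e in pred if e.label == label]
        remaining = list(g)
        tp = 0
        for key in p:
            if key in remaining:
                remaining.remove(key)
                tp += 1
        counts[label] = Counts(tp=tp, fp=len(p) - tp, fn=len(g) - tp)
    return counts


def _overlap(a: Entity, b: Entity) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def compare_relaxed(gold: list[Entity], pred: list[Entity]) -> MatchCounts:
    """Any-overlap + same-label counts with one-to-one greedy pairing by
    descending overlap length (ties: smaller gold start, then smaller
    predicted start)."""
    counts: MatchCounts = {}
    labels = {e.label for e in gold} | {e.label for e in pred}
    for label in labels:
        g = [e for e in gold if e.label == label]
        p = [e for e in pred if e.label == label]
        pairs = [
            (_overlap(ge, pe), gi, pi)
            for gi, ge in enumerate(g)
            for pi, pe in enumerate(p)
            if _overlap(ge, pe) > 0
        ]
        pairs.sort(key=lambda t: (-t[0], g[t[1]].start, p[t[2]].start, t[1], t[2]))
        used_g: set[int] = set()
        used_p: set[int] = set()
        tp = 0
        for _, gi, pi in pairs:
            if gi in used_g or pi in used_p:
                continue
            used_g.add(gi)
            used_p.add(pi)
            tp += 1
        counts[label] = Counts(tp=tp, fp=len(p) - tp, fn=len(g) - tp)
    return counts


def prf(counts: Counts | MatchCounts) -> Metrics:
    """Precision/recall/F1 from counts; zero denominators give 0."""
    if isinstance(counts, dict):
        total = Counts()
        for c in counts.values():
            total = total + c
        counts = total
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return Metrics(p=p, r=r, f1=f1)


def micro_average(counts: MatchCounts) -> Metrics:
    """PRF over TP/FP/FN summed across labels."""
    return prf(counts)


def merge_counts(a: MatchCounts, b: MatchCounts) -> MatchCounts:
    out = {k: Counts(c.tp, c.fp, c.fn) for k, c in a.items()}
    for k, c in b.items():
        out[k] = out.get(k, Counts()) + c
    return out


def iaa_fmeasure(
    set_a: list[Entity], set_b: list[Entity], criterion: str = "strict"
) -> Metrics:
    """Pairwise inter-annotator agreement as the F-measure between two
    annotators' entity sets (symmetric in F1 under argument swap)."""
    compare = compare_strict if criterion == "strict" else compare_relaxed
    return prf(compare(set_a, set_b))


# ---------------------------------------------------------------------------
# Attribute scoring and corpus statistics
# ---------------------------------------------------------------------------


def _attribute_units(doc: Document) -> list[Entity]:
    """Attributes as pseudo-entities (entity span, attribute type) so the
    strict entity comparison applies unchanged."""
    spans = {e.id: e for e in doc.entities}
    units = []
    for attr in doc.attributes:
        ent = spans.get(attr.target)
        if ent is None:
            continue
        units.append(
            Entity(
                id=attr.id,
                label=attr.type,
                start=ent.start,
                end=ent.end,
                surface=ent.surface,
                source=ent.source,
            )
        )
    return units


def compare_attributes(gold: Document, pred: Document) -> MatchCounts:
    """Strict scoring of attributes as (entity span, attribute type)
    units."""
    return compare_strict(_attribute_units(gold), _attribute_units(pred))


def floor2(x: float) -> float:
    """Floor to two decimals (the rounding used for per-document means)."""
    return math.floor(x * 100) / 100


def per_doc_mean(total: int, n_docs: int) -> float:
    """Mean annotations per document, floored to two decimals; exact
    integer arithmetic avoids float rounding at the boundary."""
    if n_docs == 0:
        return 0.0
    return (total * 100 // n_docs) / 100


def corpus_stats(docs: list[Document]) -> dict:
    """Totals and per-document means (two decimals, floored) of entities
    and attributes."""
    n = len(docs)
    total_entities = sum(len(d.entities) for d in docs)
    total_attributes = sum(len(d.attributes) for d in docs)
    if n == 0:
        logger.warning("corpus_stats: empty corpus, means reported as 0")
    return {
        "n_docs": n,
        "total_entities": total_entities,
        "total_attributes": total_attributes,
        "mean_entities_per_doc": per_doc_mean(total_entities, n),
        "mean_attributes_per_doc": per_doc_mean(total_attributes, n),
    }


def format_report(counts: MatchCounts) -> str:
    """Per-label and micro-average P/R/F1 table as TSV."""
    lines = ["label\ttp\tfp\tfn\tP\tR\tF1"]
    for label in sorted(counts):
        c = counts[label]
        m = prf(c)
        lines.append(
            f"{label}\t{c.tp}\t{c.fp}\t{c.fn}\t{m.p:.4f}\t{m.r:.4f}\t{m.f1:.4f}"
        )
    total = Counts()
    for c in counts.values():
        total = total + c
    m = prf(total)
    lines.append(
        f"micro\t{total.tp}\t{total.fp}\t{total.fn}\t{m.p:.4f}\t{m.r:.4f}\t{m.f1:.4f}"
    )
    return "\n".join(lines) + "\n"
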