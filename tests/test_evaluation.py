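"""Scoring: strict/relaxed matching, P/R/F1 identities, IAA symmetry,
corpus statistics."""

import random

import pytest

from clinanno.core import Entity
from clinanno.evaluation import (
    Counts,
    compare_relaxed,
    compare_strict,
    corpus_stats,
    iaa_fmeasure,
    micro_average,
    per_doc_mean,
    prf,
)


def ent(label, start, end):
    return Entity("", label, start, end, "x" * (end - start))


def rand_entities(rng, n, labels=("DISO", "PROC")):
    out = []
    for _ in range(n):
        start = rng.randrange(0, 40)
        out.append(ent(rng.choice(labels), start, start + rng.randrange(1, 6)))
    return out


class TestPrf:
    @pytest.mark.parametrize(
        "tp,fp,fn,p,r,f1",
        [
            (8, 2, 2, 0.8, 0.8, 0.8),
            (3, 1, 2, 0.75, 0.6, 2 * 0.75 * 0.6 / 1.35),
            (0, 0, 0, 0.0, 0.0, 0.0),
        ],
    )
    def test_closed_forms(self, tp, fp, fn, p, r, f1):
        m = prf(Counts(tp, fp, fn))
        assert (m.p, m.r) == (p, r)
        assert m.f1 == pytest.approx(f1)

    def test_f1_is_harmonic_mean_and_bounded(self):
        rng = random.Random(5)
        for _ in range(200):
            c = Counts(rng.randrange(0, 20), rng.randrange(0, 20), rng.randrange(0, 20))
            m = prf(c)
            if m.p + m.r:
                assert m.f1 == pytest.approx(2 * m.p * m.r / (m.p + m.r))
            assert m.f1 <= max(m.p, m.r) + 1e-12

    def test_monotone_in_tp(self):
        assert prf(Counts(5, 3, 3)).f1 >= prf(Counts(4, 3, 3)).f1


class TestCompareStrict:
    def test_identical_sets(self):
        gold = [ent("DISO", 0, 5), ent("PROC", 10, 15)]
        counts = compare_strict(gold, list(gold))
        assert all(c.fp == 0 and c.fn == 0 for c in counts.values())

    def test_shifted_span_counts_both_errors(self):
        counts = compare_strict([ent("DISO", 0, 5)], [ent("DISO", 1, 6)])
        c = counts["DISO"]
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_counts_consistent_with_totals(self):
        rng = random.Random(13)
        for _ in range(100):
            gold = rand_entities(rng, rng.randrange(0, 6))
            pred = rand_entities(rng, rng.randrange(0, 6))
            counts = compare_strict(gold, pred)
            for label, c in counts.items():
                assert c.tp + c.fn == sum(1 for e in gold if e.label == label)
                assert c.tp + c.fp == sum(1 for e in pred if e.label == label)

    def test_equals_multiset_intersection_oracle(self):
        from collections import Counter

        rng = random.Random(99)
        for _ in range(100):
            gold = rand_entities(rng, rng.randrange(0, 6))
            pred = rand_entities(rng, rng.randrange(0, 6))
            counts = compare_strict(gold, pred)
            gkeys = Counter((e.start, e.end, e.label) for e in gold)
            pkeys = Counter((e.start, e.end, e.label) for e in pred)
            oracle_tp = sum((gkeys & pkeys).values())
            assert sum(c.tp for c in counts.values()) == oracle_tp
            assert sum(c.fp for c in counts.values()) == len(pred) - oracle_tp
            assert sum(c.fn for c in counts.values()) == len(gold) - oracle_tp


class TestCompareRelaxed:
    def test_partial_overlap_same_label(self):
        counts = compare_relaxed([ent("DISO", 0, 22)], [ent("DISO", 6, 22)])
        assert counts["DISO"].tp == 1

    def test_overlap_different_label(self):
        counts = compare_relaxed([ent("DISO", 0, 10)], [ent("PROC", 0, 10)])
        assert counts["DISO"].fn == 1
        assert counts["PROC"].fp == 1

    def test_one_to_one_matching(self):
        gold = [ent("DISO", 0, 10)]
        pred = [ent("DISO", 0, 6), ent("DISO", 6, 10)]
        c = compare_relaxed(gold, pred)["DISO"]
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)

    def test_tp_bounded_by_set_sizes(self):
        rng = random.Random(17)
        for _ in range(100):
            gold = rand_entities(rng, rng.randrange(0, 6))
            pred = rand_entities(rng, rng.randrange(0, 6))
            for label, c in compare_relaxed(gold, pred).items():
                assert c.tp <= min(
                    sum(1 for e in gold if e.label == label),
                    sum(1 for e in pred if e.label == label),
                )


class TestMicroAverage:
    def test_single_label_equals_per_label(self):
        counts = {"DISO": Counts(3, 1, 2)}
        assert micro_average(counts) == prf(counts["DISO"])

    def test_two_labels_pooled(self):
        counts = {"A": Counts(1, 1, 0), "B": Counts(1, 0, 1)}
        m = micro_average(counts)
        assert m.p == m.r == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(2 / 3)

    def test_empty(self):
        m = micro_average({})
        assert (m.p, m.r, m.f1) == (0.0, 0.0, 0.0)


class TestIaa:
    def test_identical_sets_f1_one(self):
        ents = [ent("DISO", 0, 5)]
        assert iaa_fmeasure(ents, list(ents)).f1 == 1.0

    def test_disjoint_sets_f1_zero(self):
        assert iaa_fmeasure([ent("DISO", 0, 5)], [ent("DISO", 10, 15)]).f1 == 0.0

    def test_symmetry(self):
        rng = random.Random(3)
        for _ in range(100):
            a = rand_entities(rng, rng.randrange(0, 6))
            b = rand_entities(rng, rng.randrange(0, 6))
            assert iaa_fmeasure(a, b).f1 == pytest.approx(iaa_fmeasure(b, a).f1)


class TestCorpusStats:
    def test_reported_corpus_means(self):
        # the annotated corpus: 86 389 entities and 16 590 attributes over
        # 1 200 texts
        assert per_doc_mean(86389, 1200) == 71.99
        assert per_doc_mean(16590, 1200) == 13.82

    def test_small_corpus(self, make_doc):
        doc = make_doc("a b c")
        for n, tok in enumerate(doc.sentences[0].tokens, start=1):
            doc.entities.append(Entity(f"T{n}", "DISO", tok.start, tok.end, tok.surface))
        stats = corpus_stats([doc])
        assert stats["total_entities"] == 3
        assert stats["mean_entities_per_doc"] == 3.00

    def test_empty_corpus(self):
        stats = corpus_stats([])
        assert stats["mean_entities_per_doc"] == 0
        assert stats["mean_attributes_per_doc"] == 0
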