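"""Negation/speculation: cue detection, scope computation, concept-level
attribute assignment, and oracle equivalence."""

import random

import pytest

from clinanno.core import Entity
from clinanno.negspec import (
    Scope,
    assign_negspec,
    compute_scope,
    compute_scopes,
    detect_cues,
    load_triggers,
)


@pytest.fixture(scope="module")
def triggers():
    return load_triggers()


def cues_of(doc, triggers):
    return [(e.label, e.surface) for e in detect_cues(doc, triggers)]


class TestDetectCues:
    def test_negation_cue(self, make_doc, triggers):
        doc = make_doc("Los pacientes no habían recibido tratamiento antibiótico")
        assert cues_of(doc, triggers) == [("Neg_cue", "no")]

    def test_pseudo_trigger_suppresses(self, make_doc, triggers):
        doc = make_doc("No solo diabetes sino también otra cosa")
        assert cues_of(doc, triggers) == []

    def test_speculation_cue(self, make_doc, triggers):
        doc = make_doc("El paciente podría presentar fiebre")
        assert cues_of(doc, triggers) == [("Spec_cue", "podría")]

    def test_longest_trigger_wins(self, make_doc, triggers):
        doc = make_doc("Hay sospecha de recaída")
        assert cues_of(doc, triggers) == [("Spec_cue", "sospecha de")]

    def test_no_triggers_no_cues(self, make_doc):
        doc = make_doc("Sin tratamiento no hay posible mejora")
        assert detect_cues(doc, triggers=[]) == []


def scope_tokens(doc, scope):
    return doc.text[scope.start : scope.end]


class TestComputeScope:
    def _cue(self, doc, surface):
        start = doc.text.index(surface)
        return Entity("T1", "Neg_cue", start, start + len(surface), surface)

    def test_window_bounded(self, make_doc, triggers):
        doc = make_doc("no a b c d e f g h i")
        cue = self._cue(doc, "no")
        scope = compute_scope(cue, doc.sentences[0], triggers, max_window=6)
        assert scope_tokens(doc, scope).split() == ["a", "b", "c", "d", "e", "f"]

    def test_sentence_bounded(self, make_doc, triggers):
        doc = make_doc("no fiebre alta")
        cue = self._cue(doc, "no")
        scope = compute_scope(cue, doc.sentences[0], triggers, max_window=6)
        assert scope_tokens(doc, scope).split() == ["fiebre", "alta"]

    def test_termination_ends_scope(self, make_doc, triggers):
        doc = make_doc("no fiebre alta pero dolor intenso")
        cue = self._cue(doc, "no")
        scope = compute_scope(cue, doc.sentences[0], triggers, max_window=10)
        assert scope_tokens(doc, scope).split() == ["fiebre", "alta"]

    def test_cue_at_sentence_end_empty_scope(self, make_doc, triggers):
        doc = make_doc("resultado negativo no")
        cue = self._cue(doc, "no")
        scope = compute_scope(cue, doc.sentences[0], triggers, max_window=6)
        assert scope.start == scope.end == cue.end

    def test_post_cue_scope_backward(self, make_doc, triggers):
        doc = make_doc("cultivo de sangre negativo")
        start = doc.text.index("negativo")
        cue = Entity("T1", "Neg_cue", start, start + 8, "negativo")
        scope = compute_scope(
            cue, doc.sentences[0], triggers, max_window=6, direction="post"
        )
        assert scope.end == cue.start
        assert scope_tokens(doc, scope).strip().split() == ["cultivo", "de", "sangre"]


class TestAssignNegspec:
    def test_concept_level_example(self, resources, make_doc):
        """Only the treatment concept is negated; the subject is not."""
        from clinanno.pipeline import run_pipeline

        doc = run_pipeline(
            "Los pacientes no habían recibido tratamiento antibiótico",
            resources=resources,
        )
        negated = {
            doc.entity_by_id(a.target).surface
            for a in doc.attributes
            if a.type == "Negated"
        }
        assert negated == {"tratamiento antibiótico"}

    def test_entity_outside_scope_untouched(self, make_doc, triggers):
        doc = make_doc("diabetes previa y no fiebre")
        ent = Entity("T1", "DISO", 0, 8, "diabetes")
        cue_start = doc.text.index("no")
        cue = Entity("T2", "Neg_cue", cue_start, cue_start + 2, "no")
        scopes = compute_scopes(doc, [cue], triggers)
        assert assign_negspec([ent], scopes) == []

    def test_nearest_cue_wins(self, make_doc):
        # speculation cue at distance 0, negation cue further away
        doc = make_doc("w x y z diabetes")
        ent = Entity("T1", "DISO", 8, 16, "diabetes")
        neg = Scope(Entity("T2", "Neg_cue", 0, 1, "w"), "negation", 2, 16)
        spec = Scope(Entity("T3", "Spec_cue", 6, 7, "z"), "speculation", 8, 16)
        attrs = assign_negspec([ent], [neg, spec])
        assert [(a.type) for a in attrs] == ["Speculated"]

    def test_negation_beats_speculation_at_tie(self, make_doc):
        doc = make_doc("a b diabetes")
        ent = Entity("T1", "DISO", 4, 12, "diabetes")
        neg = Scope(Entity("T2", "Neg_cue", 0, 1, "a"), "negation", 2, 12)
        spec = Scope(Entity("T3", "Spec_cue", 0, 1, "a"), "speculation", 2, 12)
        attrs = assign_negspec([ent], [neg, spec])
        assert [(a.type) for a in attrs] == ["Negated"]

    def test_non_umls_labels_skipped(self, make_doc):
        ent = Entity("T1", "Result_or_Value", 2, 5, "< 3")
        scope = Scope(Entity("T2", "Neg_cue", 0, 1, "n"), "negation", 1, 10)
        assert assign_negspec([ent], [scope]) == []

    def test_null_property_no_triggers(self, resources, make_doc):
        from clinanno.negspec import detect_cues

        doc = make_doc("Sin diabetes y no fiebre posible")
        assert detect_cues(doc, triggers=[]) == []


def oracle_assign(entities, scopes):
    """Brute force: test all entity x scope containments, then apply the
    nearest-cue / negation-first precedence."""
    out = {}
    for ent in entities:
        if ent.label not in {"ANAT", "CHEM", "DEVI", "DISO", "GENE", "LIVB", "PHYS", "PROC"}:
            continue
        best = None
        for s in scopes:
            if not (s.start <= ent.start and ent.end <= s.end):
                continue
            if s.cue.end <= ent.start:
                d = ent.start - s.cue.end
            else:
                d = s.cue.start - ent.end
            rank = (d, 0 if s.polarity == "negation" else 1)
            if best is None or rank < best[0]:
                best = (rank, s.polarity)
        if best is not None:
            out[ent.id] = "Negated" if best[1] == "negation" else "Speculated"
    return out


class TestOracleEquivalence:
    def test_randomized_sentences(self, make_doc, triggers):
        rng = random.Random(77)
        cue_words = ["no", "sin", "posible", "descartar", "probable"]
        fillers = ["x", "y", "z", "w", "v", "pero", "aunque"]
        entity_words = ["diabetes", "fiebre", "asma"]
        for _ in range(120):
            words = []
            for _ in range(rng.randint(4, 14)):
                r = rng.random()
                if r < 0.2:
                    words.append(rng.choice(cue_words))
                elif r < 0.5:
                    words.append(rng.choice(entity_words))
                else:
                    words.append(rng.choice(fillers))
            doc = make_doc(" ".join(words) + ".")
            entities = []
            for sent in doc.sentences:
                for i, tok in enumerate(sent.tokens):
                    if tok.surface in entity_words:
                        entities.append(
                            Entity(f"T{len(entities)+1}", "DISO", tok.start, tok.end, tok.surface)
                        )
            cues = detect_cues(doc, triggers)
            for n, cue in enumerate(cues):
                cue.id = f"C{n+1}"
            scopes = compute_scopes(doc, cues, triggers, max_window=6)
            got = {a.target: a.type for a in assign_negspec(entities, scopes)}
            assert got == oracle_assign(entities, scopes)
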