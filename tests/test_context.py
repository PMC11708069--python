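"""ConText-style attributes: temporality, experiencer, contraindication,
Age on living-being entities."""

import pytest

from clinanno.context_attrs import (
    assign_age_attr,
    assign_contraindicated,
    assign_experiencer,
    assign_temporality,
    load_context_triggers,
)
from clinanno.core import Entity
from clinanno.pipeline import run_pipeline


@pytest.fixture(scope="module")
def triggers():
    return load_context_triggers()


def make_entities(doc, pairs):
    ents = []
    for n, (surface, label) in enumerate(pairs, start=1):
        start = doc.text.index(surface)
        ents.append(Entity(f"T{n}", label, start, start + len(surface), surface))
    return ents


def attr_map(doc, attrs, ents):
    by_id = {e.id: e for e in ents}
    return {(by_id[a.target].surface, a.type) for a in attrs}


class TestTemporality:
    def test_history_of(self, make_doc, triggers):
        doc = make_doc("Antecedentes de diabetes en la familia lejana.")
        ents = make_entities(doc, [("diabetes", "DISO")])
        attrs = assign_temporality(doc, ents, triggers)
        assert attr_map(doc, attrs, ents) == {("diabetes", "History_of")}

    def test_family_history_beats_history(self, make_doc, triggers):
        doc = make_doc("Antecedentes familiares de diabetes.")
        ents = make_entities(doc, [("diabetes", "DISO")])
        attrs = assign_temporality(doc, ents, triggers)
        assert attr_map(doc, attrs, ents) == {("diabetes", "Family_History_of")}

    def test_future_suffix_heuristic(self, make_doc, triggers):
        doc = make_doc("Se administrará quimioterapia.")
        ents = make_entities(doc, [("quimioterapia", "PROC")])
        attrs = assign_temporality(doc, ents, triggers, future_suffix=True)
        assert attr_map(doc, attrs, ents) == {("quimioterapia", "Future")}

    def test_future_suffix_toggleable(self, make_doc, triggers):
        doc = make_doc("Se administrará quimioterapia.")
        ents = make_entities(doc, [("quimioterapia", "PROC")])
        assert assign_temporality(doc, ents, triggers, future_suffix=False) == []

    def test_hypothetical(self, make_doc, triggers):
        doc = make_doc("En caso de cirugía avisar.")
        ents = make_entities(doc, [("cirugía", "PROC")])
        attrs = assign_temporality(doc, ents, triggers)
        assert attr_map(doc, attrs, ents) == {("cirugía", "Hypothetical")}

    def test_no_trigger_no_attribute(self, make_doc, triggers):
        doc = make_doc("El paciente presenta diabetes.")
        ents = make_entities(doc, [("diabetes", "DISO")])
        assert assign_temporality(doc, ents, triggers) == []

    def test_at_most_one_temporality(self, make_doc, triggers):
        doc = make_doc("Antecedentes de diabetes que se tratará.")
        ents = make_entities(doc, [("diabetes", "DISO")])
        attrs = assign_temporality(doc, ents, triggers)
        assert len(attrs) == 1

    def test_empty_tables_null(self, make_doc):
        doc = make_doc("Antecedentes de diabetes.")
        ents = make_entities(doc, [("diabetes", "DISO")])
        assert assign_temporality(doc, ents, triggers=[], future_suffix=False) == []


class TestExperiencer:
    @pytest.mark.parametrize(
        "surface,expected",
        [
            ("pacientes", "Patient"),
            ("madre", "Family_member"),
            ("investigador", "Other"),
        ],
    )
    def test_lists(self, make_doc, surface, expected):
        doc = make_doc(f"Aviso para {surface} del estudio.")
        ents = make_entities(doc, [(surface, "LIVB")])
        attrs = assign_experiencer(doc, ents)
        assert attr_map(doc, attrs, ents) == {(surface, expected)}

    def test_unlisted_livb_stays_bare(self, make_doc):
        doc = make_doc("Presencia de virus en sangre.")
        ents = make_entities(doc, [("virus", "LIVB")])
        assert assign_experiencer(doc, ents) == []

    def test_non_livb_skipped(self, make_doc):
        doc = make_doc("paciente")
        ents = [Entity("T1", "DISO", 0, 8, "paciente")]
        assert assign_experiencer(doc, ents) == []


class TestContraindicated:
    def test_chem_example(self, resources):
        doc = run_pipeline(
            "Pacientes con contraindicación a corticoesteroides", resources=resources
        )
        contra = {
            doc.entity_by_id(a.target).surface
            for a in doc.attributes
            if a.type == "Contraindicated"
        }
        assert contra == {"corticoesteroides"}

    def test_proc_target(self, make_doc, triggers):
        doc = make_doc("Presenta contraindicación para cirugía abdominal.")
        ents = make_entities(doc, [("cirugía", "PROC")])
        attrs = assign_contraindicated(doc, ents, triggers)
        assert attr_map(doc, attrs, ents) == {("cirugía", "Contraindicated")}

    def test_no_target_in_window(self, make_doc, triggers):
        doc = make_doc("Existe contraindicación conocida.")
        ents = make_entities(doc, [("conocida", "DISO")])
        assert assign_contraindicated(doc, ents, triggers) == []

    def test_negated_trigger_suppressed(self, make_doc, triggers):
        doc = make_doc("Sin contraindicación a corticoesteroides.")
        ents = make_entities(doc, [("corticoesteroides", "CHEM")])
        assert assign_contraindicated(doc, ents, triggers) == []


class TestAgeAttribute:
    @pytest.mark.parametrize(
        "surface,expected", [("adultos", True), ("niños", True), ("pacientes", False)]
    )
    def test_age_terms(self, make_doc, surface, expected):
        doc = make_doc(f"Estudio en {surface} sanos.")
        ents = make_entities(doc, [(surface, "LIVB")])
        attrs = assign_age_attr(ents)
        assert bool(attrs) is expected
        if attrs:
            assert attrs[0].type == "Age"
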