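"""Synthetic test resources: a toy Spanish medical lexicon, a generator of
gold-annotated documents, and synonym-replacement augmentation.

Everything here is synthetic.  The toy lexicon imitates the structure of a
real medical lexicon (lemmas, variants, semantic groups, CUIs, SNOMED CT
codes, abbreviation flags) with a few dozen entries; codes are
plausible-looking identifiers, not an excerpt of any licensed resource.
The document generator assembles texts from a fixed template grammar that
uses only toy-lexicon vocabulary and packaged trigger cues, so each
document carries exact gold entities and attributes for every annotation
layer, and the full rule pipeline reproduces the gold standard — the
central end-to-end check of the package.

Two templates are fixed wording rather than generated: the negation
sentence "Los pacientes no habían recibido tratamiento antibiótico." and
the contraindication sentence "Pacientes con contraindicación a
corticoesteroides.", the canonical worked examples for concept-level
negation and for the Contraindicated attribute.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .core import Attribute, Document, Entity, RuleTokenizer, make_document, segment
from .lexicon import Lexicon, fold, parse_lexicon

_LAYER_ORDER = {"umls": 0, "temporal": 1, "medication": 2, "misc": 3, "cues": 4}

# lemma, variants, groups, cuis, snomed, is_abbrev  (synthetic fixture data)
_TOY_ROWS = [
    ("brazo", "brazo|brazos", "ANAT", "C0446516", "40983000", "0"),
    ("aspirina", "aspirina", "CHEM", "C0004057", "7947003", "0"),
    (
        "corticoesteroide",
        "corticoesteroides|corticoesteroide|corticosteroides|corticosteroide",
        "CHEM",
        "C0001617",
        "79440004",
        "0",
    ),
    ("bilirrubina", "bilirrubina", "CHEM", "C0005437", "79706000", "0"),
    ("diabetes", "diabetes", "DISO", "C0011849", "73211009", "0"),
    ("diabetes mellitus", "diabetes mellitus", "DISO", "C0011849", "73211009", "0"),
    (
        "tratamiento antibiótico",
        "tratamiento antibiótico|tratamiento antibiotico",
        "PROC",
        "C0338237",
        "",
        "0",
    ),
    ("quimioterapia", "quimioterapia", "PROC", "C0013216", "367336001", "0"),
    ("radioterapia", "radioterapia", "PROC", "C0034619", "108290001", "0"),
    ("cirugía", "cirugía|cirugia|cirugías|cirugias", "PROC", "C0038895", "387713003", "0"),
    ("sonda", "sonda|sondas", "DEVI", "C0183683", "", "0"),
    ("BRAF", "BRAF", "GENE", "C0812241", "", "1"),
    ("respiración", "respiración|respiracion", "PHYS", "C0035203", "", "0"),
    ("paciente", "paciente|pacientes", "LIVB", "C0030705", "116154003", "0"),
    ("madre", "madre|madres", "LIVB", "C0026591", "", "0"),
    ("investigador", "investigador|investigadores", "LIVB", "C0035173", "", "0"),
    ("adulto", "adulto|adultos|adulta|adultas", "LIVB", "C0001675", "", "0"),
    ("niño", "niño|niños|niña|niñas", "LIVB", "C0008059", "", "0"),
    ("ejercicio físico", "ejercicio físico|ejercicio fisico", "ACTI", "C0015259", "", "0"),
    ("calidad de vida", "calidad de vida", "CONC", "C0034380", "", "0"),
    ("soja", "soja", "Food_or_Drink", "C0037733", "", "0"),
    ("recaída", "recaída|recaida|recaídas|recaidas", "Observation_or_Finding", "C0035020", "", "0"),
    ("intravenoso", "intravenoso|intravenosa", "Route", "C1522726", "", "0"),
    ("IV", "IV", "Route", "C1522726", "", "1"),
]


def toy_lexicon_text(seed: int = 0) -> str:
    """Toy lexicon file content (TSV).  Deterministic for any seed — the
    fixture vocabulary is fixed; the seed is accepted for interface
    symmetry with the corpus generator."""
    del seed
    header = "lemma\tvariants\tgroups\tcuis\tsnomed\tis_abbrev"
    return "\n".join([header] + ["\t".join(row) for row in _TOY_ROWS]) + "\n"


def gen_toy_lexicon(seed: int = 0, path=None) -> str:
    """Write (or return) the toy lexicon TSV; same seed → identical file."""
    text = toy_lexicon_text(seed)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def toy_lexicon(seed: int = 0) -> Lexicon:
    return parse_lexicon(toy_lexicon_text(seed))


# ---------------------------------------------------------------------------
# Template grammar
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ann:
    """An annotated segment of a template: surface, entity label, the
    attribute types the pipeline assigns to it, and its UMLS CUI (empty for
    rule-layer entities)."""

    surface: str
    label: str
    attrs: tuple[str, ...] = ()
    cui: str = ""


# each template is one sentence: a sequence of plain strings and Ann parts
TEMPLATES: list[tuple] = [
    # fixed worked examples
    (
        "Los ",
        Ann("pacientes", "LIVB", ("Patient",), "C0030705"),
        " ",
        Ann("no", "Neg_cue"),
        " habían recibido ",
        Ann("tratamiento antibiótico", "PROC", ("Negated",), "C0338237"),
        ".",
    ),
    (
        Ann("Pacientes", "LIVB", ("Patient",), "C0030705"),
        " con contraindicación a ",
        Ann("corticoesteroides", "CHEM", ("Contraindicated",), "C0001617"),
        ".",
    ),
    # temporal
    ("El fármaco se administró durante ", Ann("dos horas", "Duration"), "."),
    (
        "Se administrará ",
        Ann("quimioterapia", "PROC", ("Future",), "C0013216"),
        " ",
        Ann("semanalmente", "Frequency"),
        ".",
    ),
    (
        "Mayores de ",
        Ann("18 años", "Age"),
        " con ",
        Ann("diabetes", "DISO", (), "C0011849"),
        ".",
    ),
    ("Ensayo registrado en ", Ann("2022", "Date"), "."),
    (
        "Control ",
        Ann("posoperatorio", "Date"),
        " con ",
        Ann("sonda", "DEVI", (), "C0183683"),
        ".",
    ),
    (
        "Consumo de ",
        Ann("soja", "Food_or_Drink", (), "C0037733"),
        " ",
        Ann("por la noche", "Time"),
        ".",
    ),
    (
        Ann("Calidad de vida", "CONC", (), "C0034380"),
        " evaluada ",
        Ann("mensualmente", "Frequency"),
        ".",
    ),
    # medication
    (
        "Dosis de ",
        Ann("125 mg", "Dose"),
        " por ",
        Ann("vía oral", "Route"),
        " en forma de ",
        Ann("píldora", "Form"),
        ".",
    ),
    (
        "Se administró ",
        Ann("aspirina", "CHEM", (), "C0004057"),
        " ",
        Ann("IV", "Route"),
        ".",
    ),
    (
        "Dosis de ",
        Ann("5 mg/kg", "Dose"),
        " ",
        Ann("cada ocho horas", "Frequency"),
        ".",
    ),
    # temporality / experiencer
    (
        "Antecedentes de ",
        Ann("diabetes mellitus", "DISO", ("History_of",), "C0011849"),
        ".",
    ),
    (
        "Antecedentes familiares de ",
        Ann("diabetes", "DISO", ("Family_History_of",), "C0011849"),
        ".",
    ),
    (
        "La ",
        Ann("madre", "LIVB", ("Family_member",), "C0026591"),
        " del ",
        Ann("paciente", "LIVB", ("Patient",), "C0030705"),
        " presentaba ",
        Ann("recaída", "Observation_or_Finding", (), "C0035020"),
        ".",
    ),
    (
        "En caso de ",
        Ann("cirugía", "PROC", ("Hypothetical",), "C0038895"),
        ", contacte al ",
        Ann("investigador", "LIVB", ("Other",), "C0035173"),
        ".",
    ),
    # negation / speculation
    (
        Ann("Sin", "Neg_cue"),
        " ",
        Ann("diabetes", "DISO", ("Negated",), "C0011849"),
        " documentada.",
    ),
    (
        Ann("Sospecha de", "Spec_cue"),
        " ",
        Ann("recaída", "Observation_or_Finding", (), "C0035020"),
        " y ",
        Ann("diabetes", "DISO", ("Speculated",), "C0011849"),
        ".",
    ),
    ("No solo ", Ann("diabetes", "DISO", (), "C0011849"), "."),
    # miscellaneous
    (
        Ann("Bilirrubina", "CHEM", (), "C0005437"),
        " ",
        Ann("< 3 UNL", "Result_or_Value"),
        ".",
    ),
    (
        Ann("Al menos 4", "Quantifier_or_Qualifier"),
        " ciclos de ",
        Ann("quimioterapia", "PROC", (), "C0013216"),
        ".",
    ),
    (
        Ann("Adultos", "LIVB", ("Age",), "C0001675"),
        " con ",
        Ann("diabetes", "DISO", (), "C0011849"),
        " ",
        Ann("grave", "Quantifier_or_Qualifier"),
        ".",
    ),
    # extra UMLS material
    ("Se recomienda ", Ann("ejercicio físico", "ACTI", (), "C0015259"), "."),
    ("Mutación del gen ", Ann("BRAF", "GENE", (), "C0812241"), "."),
    (
        "Dolor en el ",
        Ann("brazo", "ANAT", (), "C0446516"),
        " tras ",
        Ann("radioterapia", "PROC", (), "C0034619"),
        ".",
    ),
    (
        Ann("Respiración", "PHYS", (), "C0035203"),
        " normal en ",
        Ann("pacientes", "LIVB", ("Patient",), "C0030705"),
        " ",
        Ann("adultos", "LIVB", ("Age",), "C0001675"),
        ".",
    ),
]

# bucket indices guaranteeing at least one entity per layer in every document
_BUCKETS = {
    "cues": [0, 16, 17],
    "temporal": [2, 3, 4, 5, 6, 7, 8],
    "medication": [9, 10, 11],
    "misc": [19, 20, 21],
    "umls": [1, 12, 13, 14, 15, 22, 23, 24, 25],
}


def _layer(label: str) -> str:
    from .core import layer_of

    return layer_of(label)


def build_doc_from_templates(doc_id: str, template_ids: list[int]) -> Document:
    """Assemble one gold document from template indices (sentences joined
    by a single space)."""
    parts: list[str] = []
    ents: list[Entity] = []
    attr_specs: list[tuple[int, str]] = []  # (entity index, attr type)
    pos = 0
    for k, tid in enumerate(template_ids):
        if k > 0:
            parts.append(" ")
            pos += 1
        for item in TEMPLATES[tid]:
            if isinstance(item, Ann):
                ent = Entity(
                    id="",
                    label=item.label,
                    start=pos,
                    end=pos + len(item.surface),
                    surface=item.surface,
                    codes=[("UMLS", item.cui)] if item.cui else [],
                    source="gold",
                )
                for atype in item.attrs:
                    attr_specs.append((len(ents), atype))
                ents.append(ent)
                parts.append(item.surface)
                pos += len(item.surface)
            else:
                parts.append(item)
                pos += len(item)
    text = "".join(parts)
    doc = make_document(doc_id, text)
    segment(doc, RuleTokenizer())
    order = sorted(
        range(len(ents)),
        key=lambda i: (ents[i].start, ents[i].end, _LAYER_ORDER[ents[i].layer], ents[i].label),
    )
    id_of = {}
    for n, i in enumerate(order, start=1):
        ents[i].id = f"T{n}"
        id_of[i] = f"T{n}"
    doc.entities = [ents[i] for i in order]
    for n, (ei, atype) in enumerate(
        sorted(attr_specs, key=lambda s: (id_of[s[0]], s[1])), start=1
    ):
        doc.attributes.append(Attribute(id=f"A{n}", type=atype, target=id_of[ei]))
    return doc


def gen_gold_corpus(seed: int, n_docs: int) -> list[Document]:
    """Generate ``n_docs`` gold-annotated documents, deterministic per seed.

    Each document draws one template per annotation layer bucket (so every
    layer is populated) plus a few extra templates, without repetition.
    """
    rng = random.Random(seed)
    docs = []
    for d in range(n_docs):
        chosen: list[int] = []
        for bucket in ("cues", "temporal", "medication", "misc", "umls"):
            pick = rng.choice(_BUCKETS[bucket])
            if pick not in chosen:
                chosen.append(pick)
        remaining = [i for i in range(len(TEMPLATES)) if i not in chosen]
        chosen += rng.sample(remaining, k=rng.randint(1, 3))
        rng.shuffle(chosen)
        docs.append(build_doc_from_templates(f"doc{d:04d}", chosen))
    return docs


# ---------------------------------------------------------------------------
# Synonym-replacement augmentation
# ---------------------------------------------------------------------------


def _synonym_pool(surface: str, codes: list, lexicon: Lexicon) -> list[str]:
    """Lexicon variants sharing a CUI with the given surface/codes,
    excluding fold-equivalent forms of the surface itself."""
    cuis = {c for s, c in codes if s == "UMLS"}
    key = " ".join(fold(t, lexicon.fold_config) for t in surface.split())
    for source in (lexicon.index.get(key, []), lexicon.abbrev_index.get(surface, [])):
        for idx in source:
            cuis.update(lexicon.entries[idx].cuis)
    if not cuis:
        return []
    pool = []
    folded_self = key
    for entry in lexicon.entries:
        if not cuis.intersection(entry.cuis):
            continue
        for variant in entry.variants:
            vkey = " ".join(fold(t, lexicon.fold_config) for t in variant.split())
            if vkey != folded_self and variant not in pool:
                pool.append(variant)
    return pool


def augment_by_synonym(doc: Document, lexicon: Lexicon, seed: int) -> Document:
    """Document variant with entity surfaces replaced by lexicon variants
    that share a CUI (e.g. "intravenoso" → "IV"); labels and attributes are
    preserved and all offsets recomputed.  Entities without a synonym stay
    unchanged."""
    rng = random.Random(seed)
    ents = sorted(doc.entities, key=lambda e: (e.start, e.end))
    replacements: dict[str, str] = {}
    prev_end = -1
    for ent in ents:
        if ent.start < prev_end:  # nested/overlapping spans stay unchanged
            continue
        pool = _synonym_pool(ent.surface, ent.codes, lexicon)
        if pool:
            replacements[ent.id] = rng.choice(sorted(pool))
        prev_end = ent.end

    new_parts: list[str] = []
    new_entities: list[Entity] = []
    pos_old = 0
    pos_new = 0
    for ent in ents:
        if ent.start < pos_old:
            continue
        new_parts.append(doc.text[pos_old : ent.start])
        pos_new += ent.start - pos_old
        new_surface = replacements.get(ent.id, ent.surface)
        new_entities.append(
            Entity(
                id=ent.id,
                label=ent.label,
                start=pos_new,
                end=pos_new + len(new_surface),
                surface=new_surface,
                codes=list(ent.codes),
                source=ent.source,
                score=ent.score,
            )
        )
        new_parts.append(new_surface)
        pos_new += len(new_surface)
        pos_old = ent.end
    new_parts.append(doc.text[pos_old:])
    new_text = "".join(new_parts)

    new_doc = make_document(doc.doc_id + "-aug", new_text)
    segment(new_doc, RuleTokenizer())
    new_doc.entities = new_entities
    new_doc.attributes = [
        Attribute(id=a.id, type=a.type, target=a.target) for a in doc.attributes
    ]
    return new_doc
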