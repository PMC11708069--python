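"""Dictionary matcher: loading, folding, longest match, oracle equivalence."""

import random

import pytest

from clinanno.core import ConfigurationError, ENTITY_LABELS
from clinanno.lexicon import (
    FoldConfig,
    LexiconFormatError,
    fold,
    match_entities,
    normalize_entity,
    parse_lexicon,
)

HEADER = "lemma\tvariants\tgroups\tcuis\tsnomed\tis_abbrev"


def mk_lex(*rows):
    return parse_lexicon("\n".join([HEADER] + list(rows)))


class TestLoadLexicon:
    def test_two_rows(self):
        lex = mk_lex(
            "diabetes\tdiabetes\tDISO\tC0011849\t73211009\t0",
            "aspirina\taspirina\tCHEM\tC0004057\t\t0",
        )
        assert len(lex.entries) == 2

    def test_duplicate_rows_merged_with_unioned_codes(self):
        lex = mk_lex(
            "diabetes\tdiabetes\tDISO\tC0011849\t\t0",
            "diabetes\tdiabetes\tDISO\tC9999999\t\t0",
        )
        assert len(lex.entries) == 1
        assert sorted(lex.entries[0].cuis) == ["C0011849", "C9999999"]

    def test_malformed_cui_rejected(self):
        with pytest.raises(LexiconFormatError, match="line 2"):
            mk_lex("x\tx\tDISO\tX123\t\t0")

    def test_missing_column_names_line(self):
        with pytest.raises(LexiconFormatError, match="line 2"):
            mk_lex("solo_tres\tcolumnas\tDISO")

    def test_bad_header(self):
        with pytest.raises(LexiconFormatError, match="line 1"):
            parse_lexicon("a\tb\n")


class TestFold:
    def test_lowercases(self):
        assert fold("Diabetes") == "diabetes"

    def test_accent_strip(self):
        assert fold("FÁRMACO") == "farmaco"

    def test_accent_fold_off(self):
        assert fold("FÁRMACO", FoldConfig(accent_fold=False)) == "fármaco"

    def test_enye_preserved(self):
        assert fold("Años") == "años"


class TestMatchEntities:
    def test_simple_match(self, lexicon, make_doc):
        doc = make_doc("paciente con diabetes")
        ents = match_entities(doc, lexicon)
        assert ("DISO", "diabetes") in {(e.label, e.surface) for e in ents}

    def test_longest_match_wins(self, lexicon, make_doc):
        doc = make_doc("diabetes mellitus tipo 2")
        ents = [e for e in match_entities(doc, lexicon) if e.label == "DISO"]
        assert [(e.surface) for e in ents] == ["diabetes mellitus"]

    def test_excluded_group_dropped(self, lexicon, make_doc):
        doc = make_doc("Se recomienda ejercicio físico.")
        with_acti = match_entities(doc, lexicon)
        without = match_entities(doc, lexicon, excluded_groups={"ACTI"})
        assert any(e.label == "ACTI" for e in with_acti)
        assert not any(e.label == "ACTI" for e in without)

    def test_exclusion_does_not_change_other_groups(self, lexicon, make_doc):
        doc = make_doc("Paciente con diabetes y ejercicio físico tras radioterapia.")
        base = {
            (e.label, e.start, e.end)
            for e in match_entities(doc, lexicon)
            if e.label != "ACTI"
        }
        excl = {
            (e.label, e.start, e.end)
            for e in match_entities(doc, lexicon, excluded_groups={"ACTI"})
        }
        assert base == excl

    def test_abbreviation_case_sensitive(self, lexicon, make_doc):
        hit = match_entities(make_doc("gen BRAF"), lexicon)
        miss = match_entities(make_doc("gen braf"), lexicon)
        assert any(e.label == "GENE" for e in hit)
        assert not any(e.label == "GENE" for e in miss)

    def test_accent_insensitive_surface(self, lexicon, make_doc):
        ents = match_entities(make_doc("cirugia programada"), lexicon)
        assert any(e.label == "PROC" and e.surface == "cirugia" for e in ents)

    def test_unsegmented_doc_rejected(self, lexicon):
        from clinanno.core import make_document

        with pytest.raises(ValueError):
            match_entities(make_document("d", "diabetes"), lexicon)

    def test_no_cross_sentence_span(self, lexicon, make_doc):
        # "diabetes mellitus" split by a sentence boundary must not match
        doc = make_doc("Tiene diabetes. Mellitus no es una palabra aislada aquí.")
        ents = [e for e in match_entities(doc, lexicon) if e.label == "DISO"]
        assert [e.surface for e in ents] == ["diabetes"]


def oracle_match(doc, lexicon):
    """Independent matcher: enumerate every token n-gram with a lexicon hit,
    then keep maximal spans leftmost-first."""
    spans = []
    for sent in doc.sentences:
        toks = sent.tokens
        hits = []
        for i in range(len(toks)):
            for n in range(1, min(lexicon.max_len, len(toks) - i) + 1):
                window = toks[i : i + n]
                raw = " ".join(t.surface for t in window)
                folded = " ".join(fold(t.surface) for t in window)
                lemma = " ".join(fold(t.lemma or t.surface) for t in window)
                idxs = list(lexicon.abbrev_index.get(raw, []))
                idxs += [j for j in lexicon.index.get(folded, []) if j not in idxs]
                idxs += [j for j in lexicon.index.get(lemma, []) if j not in idxs]
                if idxs:
                    hits.append((window[0].start, window[-1].end, idxs))
        hits.sort(key=lambda h: (h[0], -(h[1] - h[0])))
        kept = []
        for start, end, idxs in hits:
            if any(s < end and start < e for s, e, _ in kept):
                continue
            kept.append((start, end, idxs))
        for start, end, idxs in kept:
            groups = []
            for j in idxs:
                for g in lexicon.entries[j].groups:
                    if g not in groups:
                        groups.append(g)
            for g in groups:
                spans.append((start, end, g))
    return sorted(spans)


class TestOracleEquivalence:
    def test_randomized_documents(self, lexicon, make_doc):
        vocab = [v for e in lexicon.entries for v in e.variants]
        fillers = ["el", "la", "con", "tras", "y", "en", "del", "o"]
        rng = random.Random(20240901)
        for _ in range(100):
            words = []
            for _ in range(rng.randint(3, 18)):
                pool = vocab if rng.random() < 0.5 else fillers
                words.append(rng.choice(pool))
                if rng.random() < 0.15:
                    words.append(".")
            doc = make_doc(" ".join(words))
            got = sorted(
                (e.start, e.end, e.label) for e in match_entities(doc, lexicon)
            )
            assert got == oracle_match(doc, lexicon)


class TestNormalizeEntity:
    def test_scheme_filter(self, lexicon, make_doc):
        doc = make_doc("diabetes mellitus")
        ent = [e for e in match_entities(doc, lexicon) if e.label == "DISO"][0]
        normalize_entity(ent, lexicon, "UMLS")
        assert ent.codes == [("UMLS", "C0011849")]
        normalize_entity(ent, lexicon, "SNOMEDCT")
        assert ent.codes == [("SNOMEDCT", "73211009")]

    def test_unknown_surface_empty_codes(self, lexicon, make_doc):
        from clinanno.core import Entity

        ent = Entity("T1", "DISO", 0, 4, "cosa")
        normalize_entity(ent, lexicon, "UMLS")
        assert ent.codes == []

    def test_unknown_scheme_rejected(self, lexicon):
        from clinanno.core import Entity

        with pytest.raises(ConfigurationError):
            normalize_entity(Entity("T1", "DISO", 0, 1, "x"), lexicon, "MESH")
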