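"""Readers and writers for the interchange formats: CoNLL-style BIO,
BRAT standoff (.txt/.ann), and JSON.

BRAT line grammar written here (and accepted on read):

* entities        ``T{n}\\t{Label} {start} {end}\\t{surface}``
* attributes      ``A{n}\\t{Type} T{m}``
* normalizations  ``N{n}\\tReference T{m} {scheme}:{code}\\t{surface}``

Offsets are Unicode code points, end-exclusive, identical to the in-memory
convention, so round-trips are bit-exact modulo identifier renumbering.
BIO files are two-column tab-separated with a blank line between sentences.
"""

from __future__ import annotations

import json
import logging
import os

from .core import Attribute, Document, Entity, layer_of

logger = logging.getLogger("clinanno")


class FormatError(ValueError):
    pass


class BratIntegrityError(FormatError):
    """An .ann span does not match the .txt slice."""


# ---------------------------------------------------------------------------
# BIO
# ---------------------------------------------------------------------------


def _snap_to_tokens(ent: Entity, tokens) -> tuple[int, int] | None:
    idx = [
        i for i, t in enumerate(tokens) if t.start < ent.end and ent.start < t.end
    ]
    if not idx:
        return None
    if tokens[idx[0]].start != ent.start or tokens[idx[-1]].end != ent.end:
        logger.warning(
            "entity %r (%d-%d) snapped outward to token boundaries",
            ent.surface,
            ent.start,
            ent.end,
        )
    return idx[0], idx[-1]


def to_bio(doc: Document, layer: str) -> list[list[tuple[str, str]]]:
    """(token surface, BIO label) rows, grouped by sentence, for one layer.

    Entities not aligned to token boundaries are snapped outward with a
    logged warning; co-located duplicate spans keep the first label only.
    """
    ents = sorted(doc.entities_in_layer(layer), key=lambda e: (e.start, e.end))
    out: list[list[tuple[str, str]]] = []
    for sent in doc.sentences:
        labels = ["O"] * len(sent.tokens)
        for ent in ents:
            if ent.end <= sent.start or ent.start >= sent.end:
                continue
            snapped = _snap_to_tokens(ent, sent.tokens)
            if snapped is None:
                continue
            i, j = snapped
            if any(labels[k] != "O" for k in range(i, j + 1)):
                logger.warning("co-located entity %s dropped in BIO export", ent.id)
                continue
            labels[i] = f"B-{ent.label}"
            for k in range(i + 1, j + 1):
                labels[k] = f"I-{ent.label}"
        out.append(list(zip([t.surface for t in sent.tokens], labels)))
    return out


def bio_to_str(rows: list[list[tuple[str, str]]]) -> str:
    blocks = ["\n".join(f"{surf}\t{lab}" for surf, lab in sent) for sent in rows]
    return "\n\n".join(blocks) + "\n"


def bio_from_str(text: str) -> list[list[tuple[str, str]]]:
    rows = []
    for block in text.strip("\n").split("\n\n"):
        sent = []
        for line in block.splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"malformed BIO line: {line!r}")
            sent.append((parts[0], parts[1]))
        if sent:
            rows.append(sent)
    return rows


def from_bio(rows: list[list[tuple[str, str]]], doc: Document) -> list[Entity]:
    """Inverse of :func:`to_bio` against the document's tokenization.

    Rows must align one-to-one with the document's sentences/tokens.
    Repairs ``I-`` after ``O`` or after a different type as ``B-``.
    """
    from .model_backend import bio_to_spans  # local import avoids a cycle

    if len(rows) != len(doc.sentences):
        raise FormatError(
            f"BIO rows have {len(rows)} sentences, document has {len(doc.sentences)}"
        )
    entities: list[Entity] = []
    for sent, sent_rows in zip(doc.sentences, rows):
        if len(sent_rows) != len(sent.tokens):
            raise FormatError("BIO row/token count mismatch")
        labels = []
        for (surf, lab), tok in zip(sent_rows, sent.tokens):
            if surf != tok.surface:
                raise FormatError(
                    f"BIO surface {surf!r} does not match token {tok.surface!r}"
                )
            if lab != "O" and not (lab.startswith("B-") or lab.startswith("I-")):
                raise FormatError(f"unknown BIO label {lab!r}")
            labels.append(lab)
        try:
            entities.extend(
                bio_to_spans(doc.text, sent.tokens, labels, source="gold")
            )
        except ValueError as exc:
            raise FormatError(str(exc)) from exc
    return entities


# ---------------------------------------------------------------------------
# BRAT standoff
# ---------------------------------------------------------------------------


def brat_safe_label(label: str) -> str:
    return label.replace("/", "_or_").replace(" ", "_")


def ann_lines(doc: Document) -> list[str]:
    """Render the .ann content; identifiers are renumbered T1.., A1.., N1..
    in document order."""
    lines: list[str] = []
    id_map: dict[str, str] = {}
    ents = sorted(doc.entities, key=lambda e: (e.start, e.end, e.label))
    for n, ent in enumerate(ents, start=1):
        tid = f"T{n}"
        id_map[ent.id] = tid
        lines.append(
            f"{tid}\t{brat_safe_label(ent.label)} {ent.start} {ent.end}\t{ent.surface}"
        )
    a = 0
    for attr in doc.attributes:
        if attr.target not in id_map:
            continue
        a += 1
        lines.append(f"A{a}\t{attr.type} {id_map[attr.target]}")
    n = 0
    for ent in ents:
        for scheme, code in ent.codes:
            n += 1
            lines.append(
                f"N{n}\tReference {id_map[ent.id]} {scheme}:{code}\t{ent.surface}"
            )
    return lines


def write_brat(doc: Document, out_dir: str) -> tuple[str, str]:
    """Write ``{doc_id}.txt`` and ``{doc_id}.ann`` into ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    txt_path = os.path.join(out_dir, f"{doc.doc_id}.txt")
    ann_path = os.path.join(out_dir, f"{doc.doc_id}.ann")
    with open(txt_path, "w", encoding="utf-8") as fh:
        fh.write(doc.text)
    with open(ann_path, "w", encoding="utf-8") as fh:
        content = "\n".join(ann_lines(doc))
        fh.write(content + ("\n" if content else ""))
    return txt_path, ann_path


def read_brat(txt_path: str, ann_path: str, doc_id: str | None = None) -> Document:
    """Load a BRAT document pair; entity sources are marked ``gold``.

    Raises :class:`BratIntegrityError` when an .ann surface does not equal
    the corresponding .txt slice.
    """
    with open(txt_path, encoding="utf-8") as fh:
        text = fh.read()
    if doc_id is None:
        doc_id = os.path.splitext(os.path.basename(txt_path))[0]
    doc = Document(doc_id=doc_id, raw_text=text, text=text)
    codes_by_tid: dict[str, list[tuple[str, str]]] = {}
    with open(ann_path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("T"):
                tid, meta, surface = line.split("\t", 2)
                label, start_s, end_s = meta.rsplit(" ", 2)
                start, end = int(start_s), int(end_s)
                if text[start:end] != surface:
                    raise BratIntegrityError(
                        f"{tid}: span {start}:{end} does not match text"
                    )
                doc.entities.append(
                    Entity(
                        id=tid,
                        label=label,
                        start=start,
                        end=end,
                        surface=surface,
                        source="gold",
                    )
                )
            elif line.startswith("A"):
                aid, rest = line.split("\t", 1)
                atype, target = rest.split(" ", 1)
                doc.attributes.append(Attribute(id=aid, type=atype, target=target.strip()))
            elif line.startswith("N"):
                _, rest = line.split("\t", 1)
                ref = rest.split("\t", 1)[0]
                _, tid, scheme_code = ref.split(" ", 2)
                scheme, code = scheme_code.split(":", 1)
                codes_by_tid.setdefault(tid, []).append((scheme, code))
            elif line.startswith("#"):
                continue
            else:
                raise FormatError(f"unsupported .ann line: {line!r}")
    for ent in doc.entities:
        ent.codes = codes_by_tid.get(ent.id, [])
    return doc


# ---------------------------------------------------------------------------
# JSON
# ---------------------------------------------------------------------------


def write_json(doc: Document) -> dict:
    """Serialize a document to the tool's JSON schema (stable key order)."""
    return {
        "doc_id": doc.doc_id,
        "text": doc.text,
        "entities": [
            {
                "id": ent.id,
                "label": ent.label,
                "start": ent.start,
                "end": ent.end,
                "text": ent.surface,
                "codes": [{"scheme": s, "code": c} for s, c in ent.codes],
                "source": ent.source,
            }
            for ent in doc.entities
        ],
        "attributes": [
            {"id": a.id, "type": a.type, "target": a.target}
            for a in doc.attributes
        ],
    }


def json_dumps(doc: Document) -> str:
    return json.dumps(write_json(doc), ensure_ascii=False, indent=2) + "\n"


def read_json(data: dict | str) -> Document:
    if isinstance(data, str):
        data = json.loads(data)
    doc = Document(doc_id=data["doc_id"], raw_text=data["text"], text=data["text"])
    for e in data["entities"]:
        doc.entities.append(
            Entity(
                id=e["id"],
                label=e["label"],
                start=e["start"],
                end=e["end"],
                surface=e["text"],
                codes=[(c["scheme"], c["code"]) for c in e.get("codes", [])],
                source=e.get("source", "gold"),
            )
        )
    for a in data["attributes"]:
        doc.attributes.append(Attribute(id=a["id"], type=a["type"], target=a["target"]))
    return doc
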