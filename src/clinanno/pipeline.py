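"""Three-stage annotation pipeline, configuration and batch processing.

Stage 1: normalization, segmentation, and UMLS-group NER through the
dictionary, a token-classification model adapter, or the hybrid merge of
both.  Stage 2 (each part toggleable): temporal entities, medication
information, miscellaneous entities, negation/speculation cues and
concept-level attributes, ConText attributes.  Stage 3 is serialization
(JSON or BRAT), handled by the writers in :mod:`clinanno.formats`.

Cross-layer span collisions are resolved after stage 2 in the order
temporal → medication → misc: a Result_or_Value candidate overlapping a
Dose is dropped unless it begins with an explicit comparator (so "125 mg"
is a Dose, "≥ 50%" a Result_or_Value).

The configuration file is flat ``key = value`` text; unknown keys raise a
configuration error naming them.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from . import context_attrs as ctx
from . import medication as med_mod
from . import misc_entities as misc_mod
from . import negspec as negspec_mod
from . import temporal as temporal_mod
from .core import (
    ConfigurationError,
    Document,
    ENTITY_LABELS,
    RuleTokenizer,
    TokenizerProvider,
    UMLS_GROUPS,
    make_document,
    segment,
)
from .formats import json_dumps, write_brat
from .lexicon import Lexicon, match_entities
from .misc_entities import COMPARATORS
from .model_backend import MergePolicy, ModelAdapter, bio_to_spans, merge_hybrid

logger = logging.getLogger("clinanno")

_LAYER_ORDER = {"umls": 0, "temporal": 1, "medication": 2, "misc": 3, "cues": 4}


@dataclass
class PipelineConfig:
    backend: str = "dict"  # dict | model | hybrid
    norm: str = "umls"  # umls | snomed | none
    lexicon: bool = True
    temporal: bool = True
    medication: bool = True
    misc: bool = True
    negspec: bool = True
    attributes: bool = True
    output: str = "json"  # json | ann
    excluded_groups: frozenset = frozenset()
    max_window: int = negspec_mod.DEFAULT_MAX_WINDOW
    context_window: int = ctx.DEFAULT_CONTEXT_WINDOW
    future_suffix: bool = True

    def __post_init__(self):
        if self.backend not in {"dict", "model", "hybrid"}:
            raise ConfigurationError(f"unknown backend {self.backend!r}")
        if self.norm not in {"umls", "snomed", "none"}:
            raise ConfigurationError(f"unknown norm {self.norm!r}")
        if self.output not in {"json", "ann"}:
            raise ConfigurationError(f"unknown output {self.output!r}")
        unknown = set(self.excluded_groups) - ENTITY_LABELS
        if unknown:
            raise ConfigurationError(f"unknown excluded groups: {sorted(unknown)}")


_BOOL_KEYS = {
    "lexicon",
    "temporal",
    "medication",
    "misc",
    "negspec",
    "attributes",
    "future_suffix",
}
_STR_KEYS = {"backend", "norm", "output"}
_INT_KEYS = {"max_window", "context_window"}


def parse_config(text: str) -> PipelineConfig:
    """Parse a flat ``key = value`` configuration file."""
    values: dict = {}
    unknown: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.startswith(";"):
            continue
        if "=" not in line:
            raise ConfigurationError(f"line {lineno}: expected key = value")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key in _BOOL_KEYS:
            if raw.lower() not in {"on", "off", "true", "false", "1", "0", "yes", "no"}:
                raise ConfigurationError(f"line {lineno}: bad boolean {raw!r}")
            values[key] = raw.lower() in {"on", "true", "1", "yes"}
        elif key in _STR_KEYS:
            values[key] = raw
        elif key in _INT_KEYS:
            values[key] = int(raw)
        elif key == "excluded_groups":
            values[key] = frozenset(
                g.strip() for g in raw.split(",") if g.strip()
            )
        else:
            unknown.append(key)
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    return PipelineConfig(**values)


@dataclass
class Resources:
    """Loaded rule tables, term lists and providers shared across documents."""

    provider: TokenizerProvider = field(default_factory=RuleTokenizer)
    lexicon: Lexicon | None = None
    adapter: ModelAdapter | None = None
    temporal_rules: list = field(default_factory=temporal_mod.load_temporal_rules)
    med_lists: med_mod.MedTermLists = field(
        default_factory=med_mod.load_med_term_lists
    )
    qualifier_terms: set = field(default_factory=misc_mod.load_qualifier_terms)
    negspec_triggers: list = field(default_factory=negspec_mod.load_triggers)
    context_triggers: list = field(default_factory=ctx.load_context_triggers)
    experiencer_lists: ctx.ExperiencerLists = field(
        default_factory=ctx.load_experiencer_lists
    )
    age_terms: set = field(default_factory=ctx.load_age_terms)
    merge_policy: MergePolicy = field(default_factory=MergePolicy)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _stage1_umls(doc: Document, config: PipelineConfig, res: Resources) -> list:
    allowed = UMLS_GROUPS - config.excluded_groups
    excluded = frozenset(ENTITY_LABELS - allowed)
    dict_ents = []
    if config.lexicon and res.lexicon is not None and config.backend in {"dict", "hybrid"}:
        dict_ents = match_entities(doc, res.lexicon, excluded_groups=excluded)
    model_ents = []
    if config.backend in {"model", "hybrid"}:
        if res.adapter is None:
            raise ConfigurationError("backend requires a model adapter")
        sents = [[t.surface for t in s.tokens] for s in doc.sentences]
        for sent, (labels, scores) in zip(doc.sentences, res.adapter.predict(sents)):
            model_ents.extend(
                bio_to_spans(doc.text, sent.tokens, list(labels), list(scores))
            )
        model_ents = [e for e in model_ents if e.label in allowed]
    if config.backend == "dict":
        return dict_ents
    if config.backend == "model":
        return model_ents
    return merge_hybrid(model_ents, dict_ents, res.merge_policy)


def _apply_norm(entities: list, config: PipelineConfig) -> None:
    if config.norm == "none":
        for ent in entities:
            ent.codes = []
        return
    scheme = "UMLS" if config.norm == "umls" else "SNOMEDCT"
    for ent in entities:
        ent.codes = [(s, c) for s, c in ent.codes if s == scheme]


def _resolve_dose_result(med_ents: list, misc_ents: list) -> list:
    """Dose vs Result_or_Value collision: a comparator-led Result wins over
    the Dose it contains; otherwise the Dose wins."""
    doses = [e for e in med_ents if e.label == "Dose"]
    kept_misc = []
    drop_dose = set()
    for ent in misc_ents:
        if ent.label != "Result_or_Value":
            kept_misc.append(ent)
            continue
        clashing = [d for d in doses if d.overlaps(ent)]
        if not clashing:
            kept_misc.append(ent)
        elif ent.surface.startswith(COMPARATORS):
            kept_misc.append(ent)
            drop_dose.update(id(d) for d in clashing)
        # else: Dose wins, Result dropped
    med_kept = [e for e in med_ents if id(e) not in drop_dose]
    return med_kept, kept_misc


def run_pipeline(
    doc_text: str,
    config: PipelineConfig | None = None,
    resources: Resources | None = None,
    doc_id: str = "doc",
) -> Document:
    """Annotate one text; returns a validated, fully populated document."""
    config = config or PipelineConfig()
    res = resources or Resources()

    doc = make_document(doc_id, doc_text)
    segment(doc, res.provider)

    # stage 1 — UMLS entities
    umls_ents = _stage1_umls(doc, config, res)
    _apply_norm(umls_ents, config)

    # stage 2 — per-layer taggers (each toggleable)
    temporal_ents = (
        temporal_mod.tag_temporal(doc, res.temporal_rules) if config.temporal else []
    )
    med_ents = (
        med_mod.tag_medication(doc, res.med_lists) if config.medication else []
    )
    misc_ents = []
    if config.misc:
        misc_ents = misc_mod.tag_misc(
            doc,
            res.lexicon if config.lexicon else None,
            res.qualifier_terms,
        )
        misc_ents = [e for e in misc_ents if e.label not in config.excluded_groups]
    med_ents, misc_ents = _resolve_dose_result(med_ents, misc_ents)
    cue_ents = (
        negspec_mod.detect_cues(doc, res.negspec_triggers) if config.negspec else []
    )

    doc.entities = sorted(
        umls_ents + temporal_ents + med_ents + misc_ents + cue_ents,
        key=lambda e: (e.start, e.end, _LAYER_ORDER[e.layer], e.label),
    )
    for n, ent in enumerate(doc.entities, start=1):
        ent.id = f"T{n}"

    # stage 2 — attributes
    attrs = []
    if config.attributes:
        if config.negspec:
            scopes = negspec_mod.compute_scopes(
                doc, cue_ents, res.negspec_triggers, config.max_window
            )
            attrs += negspec_mod.assign_negspec(doc.entities, scopes)
        attrs += ctx.assign_temporality(
            doc,
            doc.entities,
            res.context_triggers,
            config.context_window,
            config.future_suffix,
        )
        attrs += ctx.assign_experiencer(doc, doc.entities, res.experiencer_lists)
        attrs += ctx.assign_contraindicated(
            doc, doc.entities, res.context_triggers, config.context_window
        )
        attrs += ctx.assign_age_attr(doc.entities, res.age_terms)

    seen: set[tuple[str, str]] = set()
    n = 0
    for attr in attrs:
        key = (attr.target, attr.type)
        if key in seen:
            continue
        seen.add(key)
        n += 1
        attr.id = f"A{n}"
        doc.attributes.append(attr)

    return doc


# ---------------------------------------------------------------------------
# Batch processing
# ---------------------------------------------------------------------------


def run_batch(
    input_path: str,
    config: PipelineConfig | None = None,
    resources: Resources | None = None,
    out_dir: str = "out",
    log_file: str | None = None,
) -> dict:
    """Annotate a .txt file or a directory of .txt files.

    One output per input (same basename, extension per configured format).
    Unreadable files are logged and skipped; the summary reports per-layer
    entity counts and the number of failures.
    """
    config = config or PipelineConfig()
    res = resources or Resources()
    if log_file:
        handler = logging.FileHandler(log_file, encoding="utf-8")
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(handler)
    os.makedirs(out_dir, exist_ok=True)

    if os.path.isdir(input_path):
        paths = sorted(
            os.path.join(input_path, f)
            for f in os.listdir(input_path)
            if f.endswith(".txt")
        )
    else:
        paths = [input_path]

    summary = {"processed": 0, "failed": 0, "files": []}
    for path in paths:
        doc_id = os.path.splitext(os.path.basename(path))[0]
        try:
            with open(path, encoding="utf-8") as fh:
                text = fh.read()
        except OSError as exc:
            logger.error("cannot read %s: %s", path, exc)
            summary["failed"] += 1
            continue
        doc = run_pipeline(text, config, res, doc_id=doc_id)
        if config.output == "json":
            out_path = os.path.join(out_dir, f"{doc_id}.json")
            with open(out_path, "w", encoding="utf-8") as fh:
                fh.write(json_dumps(doc))
        else:
            write_brat(doc, out_dir)
        layer_counts: dict = {}
        for ent in doc.entities:
            layer_counts[ent.layer] = layer_counts.get(ent.layer, 0) + 1
        logger.info(
            "%s: %d entities %s, %d attributes",
            doc_id,
            len(doc.entities),
            layer_counts,
            len(doc.attributes),
        )
        summary["processed"] += 1
        summary["files"].append(doc_id)
    return summary
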