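"""Writers (BRAT standoff, RDF N-Triples, JSON, TSV) and a BRAT reader.

Offset conventions, documented once and converted in one place:

* internal / BRAT: 0-based character offsets, end-exclusive;
* JSON output: 1-based inclusive ``from``/``to`` positions
  (``from = start + 1``, ``to = end``).

All writers are pure functions of their input: identical input yields
byte-identical output.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Optional

from .errors import ConfigurationError, IntegrityError
from .recognizer import (
    Annotation,
    EXPERIENCER_DEFAULT,
    NEGATION_DEFAULT,
    TEMPORALITY_DEFAULT,
)
from .semantic_groups import SemanticGroupMap
from .terminology import Terminology

logger = logging.getLogger(__name__)


@dataclass
class ScoredDocument:
    """A document plus its final annotation list; the unit all writers consume."""

    doc_id: str
    text: str
    annotations: list[Annotation] = field(default_factory=list)

    def validate(self) -> None:
        for a in self.annotations:
            if not (0 <= a.start < a.end <= len(self.text)):
                raise IntegrityError(
                    f"{self.doc_id}: annotation span ({a.start}, {a.end}) out of bounds"
                )
            if self.text[a.start : a.end] != a.surface:
                raise IntegrityError(
                    f"{self.doc_id}: span ({a.start}, {a.end}) reads "
                    f"{self.text[a.start:a.end]!r}, annotation says {a.surface!r}"
                )


def internal_to_external(start: int, end: int) -> tuple[int, int]:
    """0-based end-exclusive -> 1-based inclusive (JSON convention)."""
    return start + 1, end


def external_to_internal(frm: int, to: int) -> tuple[int, int]:
    return frm - 1, to


def group_resolver(
    term: Terminology, gmap: SemanticGroupMap
) -> Callable[[Annotation], Optional[str]]:
    """Resolver mapping an annotation to its concept's first mapped group."""

    def resolve(ann: Annotation) -> Optional[str]:
        if ann.concept_id not in term:
            return None
        for t in term[ann.concept_id].semantic_types:
            g = gmap.group_of(t)
            if g:
                return g
        return None

    return resolve


# ---------------------------------------------------------------------------
# BRAT standoff

_CONTEXT_ATTRIBUTES = (
    ("negation", "negated", "Negated"),
    ("experiencer", "other", "ExperiencerOther"),
    ("temporality", "historical", "Historical"),
    ("temporality", "hypothetical", "Hypothetical"),
)


def write_brat(
    sd: ScoredDocument,
    group_of: Optional[Callable[[Annotation], Optional[str]]] = None,
    terminology: Optional[Terminology] = None,
) -> tuple[str, str]:
    """Render ``sd`` as a BRAT (.txt content, .ann content) pair.

    Entity label is the annotation's resolved semantic group, falling
    back to ``Entity``; non-default context values become attribute (A)
    lines; each annotation gets a normalization (N) line pointing at its
    concept id.
    """
    sd.validate()
    ann_lines: list[str] = []
    a_counter = 0
    n_counter = 0
    for k, ann in enumerate(sd.annotations, 1):
        label = ann.group or (group_of(ann) if group_of else None) or "Entity"
        ann_lines.append(f"T{k}\t{label} {ann.start} {ann.end}\t{ann.surface}")
        for fld, value, dim in _CONTEXT_ATTRIBUTES:
            if getattr(ann, fld) == value:
                a_counter += 1
                ann_lines.append(f"A{a_counter}\t{dim} T{k}")
        pref = ann.surface
        if terminology is not None and ann.concept_id in terminology:
            pref = terminology[ann.concept_id].pref_label
        n_counter += 1
        ann_lines.append(f"N{n_counter}\tReference T{k} DICT:{ann.concept_id}\t{pref}")
    content = "\n".join(ann_lines)
    return sd.text, content + "\n" if content else ""


_T_LINE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")
_A_LINE = re.compile(r"^A\d+\t(\S+) (T\d+)$")
_N_LINE = re.compile(r"^N\d+\tReference (T\d+) ([^\t]+)\t?(.*)$")

_DIM_TO_FIELD = {
    "Negated": ("negation", "negated"),
    "ExperiencerOther": ("experiencer", "other"),
    "Historical": ("temporality", "historical"),
    "Hypothetical": ("temporality", "hypothetical"),
}


def read_brat(txt: str, ann: str, doc_id: str = "doc") -> ScoredDocument:
    """Parse a BRAT pair back into a ScoredDocument.

    Context attributes default to affirmed/patient/recent and are
    overridden by A lines; N lines supply concept ids.  Unknown line
    types are skipped with a warning.
    """
    by_tid: dict[str, Annotation] = {}
    order: list[str] = []
    for raw in ann.splitlines():
        if not raw.strip():
            continue
        m = _T_LINE.match(raw)
        if m:
            tid, label, start, end, surface = m.groups()
            start, end = int(start), int(end)
            if txt[start:end] != surface:
                raise IntegrityError(
                    f"{tid}: text slice {txt[start:end]!r} disagrees with {surface!r}"
                )
            by_tid[tid] = Annotation(
                concept_id="",
                start=start,
                end=end,
                surface=surface,
                group=None if label == "Entity" else label,
                negation=NEGATION_DEFAULT,
                experiencer=EXPERIENCER_DEFAULT,
                temporality=TEMPORALITY_DEFAULT,
            )
            order.append(tid)
            continue
        m = _A_LINE.match(raw)
        if m:
            dim, tid = m.groups()
            if tid in by_tid and dim in _DIM_TO_FIELD:
                fld, value = _DIM_TO_FIELD[dim]
                setattr(by_tid[tid], fld, value)
            continue
        m = _N_LINE.match(raw)
        if m:
            tid, ref, _pref = m.groups()
            if tid in by_tid:
                by_tid[tid].concept_id = ref.split(":", 1)[1] if ":" in ref else ref
            continue
        logger.warning("read_brat: skipping unrecognized line: %r", raw)
    return ScoredDocument(doc_id, txt, [by_tid[t] for t in order])


# ---------------------------------------------------------------------------
# RDF (N-Triples)

_IRI_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.-]*:")


def _nt_escape(s: str) -> str:
    return (
        s.replace("\\", "\\\\")
        .replace('"', '\\"')
        .replace("\n", "\\n")
        .replace("\r", "\\r")
        .replace("\t", "\\t")
    )


def _lit(value: str, datatype: Optional[str] = None) -> str:
    out = f'"{_nt_escape(value)}"'
    if datatype:
        out += f"^^<http://www.w3.org/2001/XMLSchema#{datatype}>"
    return out


def write_rdf(sd: ScoredDocument, base_iri: str) -> str:
    """Render ``sd`` as N-Triples in a Web-Annotation-like shape.

    Emits one document node plus, per annotation, exactly ten triples:
    type, target, start, end, exact surface form, body (the concept),
    score and the three context dimensions (defaults when unset).
    """
    if not _IRI_RE.match(base_iri):
        raise ConfigurationError(f"base IRI must be absolute: {base_iri!r}")
    sd.validate()
    base = base_iri.rstrip("/#")
    vocab = f"{base}/vocab#"
    doc_iri = f"<{base}/document/{sd.doc_id}>"
    lines = [
        f"{doc_iri} <http://www.w3.org/1999/02/22-rdf-syntax-ns#type> <{vocab}Document> .",
        f"{doc_iri} <{vocab}identifier> {_lit(sd.doc_id)} .",
    ]
    for k, a in enumerate(sd.annotations, 1):
        node = f"<{base}/document/{sd.doc_id}/annotation/{k}>"
        body = (
            f"<{a.concept_id}>" if _IRI_RE.match(a.concept_id) else _lit(a.concept_id)
        )
        score = a.score if a.score is not None else 0.0
        lines += [
            f"{node} <http://www.w3.org/1999/02/22-rdf-syntax-ns#type> <{vocab}Annotation> .",
            f"{node} <{vocab}target> {doc_iri} .",
            f"{node} <{vocab}start> {_lit(str(a.start), 'integer')} .",
            f"{node} <{vocab}end> {_lit(str(a.end), 'integer')} .",
            f"{node} <{vocab}exact> {_lit(a.surface)} .",
            f"{node} <{vocab}body> {body} .",
            f"{node} <{vocab}score> {_lit(repr(float(score)), 'decimal')} .",
            f"{node} <{vocab}negation> {_lit(a.negation or NEGATION_DEFAULT)} .",
            f"{node} <{vocab}experiencer> {_lit(a.experiencer or EXPERIENCER_DEFAULT)} .",
            f"{node} <{vocab}temporality> {_lit(a.temporality or TEMPORALITY_DEFAULT)} .",
        ]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# JSON

def write_json(sd: ScoredDocument, terminology: Optional[Terminology] = None) -> str:
    """One record per concept with 1-based inclusive from/to positions."""
    sd.validate()
    by_concept: dict[str, list[Annotation]] = {}
    for a in sd.annotations:
        by_concept.setdefault(a.concept_id, []).append(a)
    records = []
    for cid, group in by_concept.items():
        pref = group[0].surface
        if terminology is not None and cid in terminology:
            pref = terminology[cid].pref_label
        ann_records = []
        for a in group:
            frm, to = internal_to_external(a.start, a.end)
            ann_records.append(
                {
                    "from": frm,
                    "to": to,
                    "matchType": a.match_type,
                    "text": a.surface,
                    "negationContext": a.negation,
                    "experiencerContext": a.experiencer,
                    "temporalityContext": a.temporality,
                }
            )
        records.append(
            {
                "annotatedConcept": {"id": cid, "prefLabel": pref},
                "score": group[0].score,
                "annotations": ann_records,
            }
        )
    return json.dumps(records, indent=2, ensure_ascii=False) + "\n"


# ---------------------------------------------------------------------------
# TSV

TSV_COLUMNS = (
    "doc_id",
    "concept_id",
    "start",
    "end",
    "surface",
    "match_type",
    "score",
    "negation",
    "experiencer",
    "temporality",
)


def write_tsv(sd: ScoredDocument) -> str:
    """Flat evaluation-friendly table, one row per annotation."""
    sd.validate()
    lines = ["\t".join(TSV_COLUMNS)]
    for a in sd.annotations:
        lines.append(
            "\t".join(
                [
                    sd.doc_id,
                    a.concept_id,
                    str(a.start),
                    str(a.end),
                    a.surface,
                    a.match_type,
                    "" if a.score is None else repr(float(a.score)),
                    a.negation or "",
                    a.experiencer or "",
                    a.temporality or "",
                ]
            )
        )
    return "\n".join(lines) + "\n"
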