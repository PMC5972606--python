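"""Terminology loading, validation and indexing.

The canonical dictionary format is a TSV file with header columns
``id``, ``pref_label``, ``synonyms``, ``semantic_types``, ``parents`` and
``source``.  Multi-valued cells are pipe-separated; literal pipes inside
labels are therefore not supported.  A minimal SKOS Turtle reader
(``skos:prefLabel`` / ``skos:altLabel`` / ``skos:broader`` only) is also
provided for vocabularies expressed in that profile.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from ._tokenize import normalize_label
from .errors import ConceptLookupError, FormatError, ValidationError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("id", "pref_label", "synonyms", "semantic_types", "parents", "source")

MATCH_PREF = "PREF"
MATCH_SYN = "SYN"


@dataclass
class Concept:
    """One terminology entry.

    ``synonyms`` never contains the preferred label and holds no
    duplicates; both are enforced on construction.
    """

    id: str
    pref_label: str
    synonyms: list[str] = field(default_factory=list)
    semantic_types: list[str] = field(default_factory=list)
    parents: list[str] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("concept id must be a non-empty string")
        if not self.pref_label:
            raise ValidationError(f"concept {self.id!r}: pref_label must be non-empty")
        seen: set[str] = set()
        deduped = []
        for syn in self.synonyms:
            if syn and syn != self.pref_label and syn not in seen:
                seen.add(syn)
                deduped.append(syn)
        self.synonyms = deduped
        if self.id in self.parents:
            logger.warning("concept %s lists itself as parent; dropped", self.id)
            self.parents = [p for p in self.parents if p != self.id]


class Terminology:
    """Concept map plus a normalized-label index.

    ``label_index`` maps the normalized form of every preferred label and
    synonym to a list of ``(concept_id, match_type)`` pairs.
    """

    def __init__(self, concepts: Iterable[Concept]):
        self.concepts: dict[str, Concept] = {}
        dupes = []
        for c in concepts:
            if c.id in self.concepts:
                dupes.append(c.id)
            self.concepts[c.id] = c
        if dupes:
            raise ValidationError(f"duplicate concept ids: {sorted(set(dupes))}")
        self._drop_dangling_parents()
        self.label_index: dict[str, list[tuple[str, str]]] = {}
        for c in self.concepts.values():
            self._index_label(c.pref_label, c.id, MATCH_PREF)
            for syn in c.synonyms:
                self._index_label(syn, c.id, MATCH_SYN)

    def _drop_dangling_parents(self) -> None:
        for c in self.concepts.values():
            kept = []
            for p in c.parents:
                if p in self.concepts:
                    kept.append(p)
                else:
                    logger.warning("concept %s: dangling parent %s dropped", c.id, p)
            c.parents = kept

    def _index_label(self, label: str, cid: str, match_type: str) -> None:
        norm = normalize_label(label)
        if not norm:
            logger.warning("concept %s: label %r normalizes to nothing; skipped", cid, label)
            return
        entries = self.label_index.setdefault(norm, [])
        if (cid, MATCH_PREF) in entries:
            return
        if match_type == MATCH_PREF and (cid, MATCH_SYN) in entries:
            entries.remove((cid, MATCH_SYN))
        if (cid, match_type) not in entries:
            entries.append((cid, match_type))

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, cid: str) -> bool:
        return cid in self.concepts

    def __getitem__(self, cid: str) -> Concept:
        try:
            return self.concepts[cid]
        except KeyError:
            raise ConceptLookupError(f"unknown concept id: {cid!r}") from None


def ancestors(term: Terminology, cid: str, max_depth: int) -> list[tuple[str, int]]:
    """Transitive is_a parents of ``cid`` up to ``max_depth``.

    Breadth-first, so each ancestor is reported once at its minimum
    distance; cycles terminate via the visited set.  Results are ordered
    by (distance, id).
    """
    if cid not in term:
        raise ConceptLookupError(f"unknown concept id: {cid!r}")
    out: list[tuple[str, int]] = []
    visited = {cid}
    queue: deque[tuple[str, int]] = deque((p, 1) for p in term[cid].parents)
    while queue:
        node, dist = queue.popleft()
        if node in visited or dist > max_depth:
            continue
        visited.add(node)
        out.append((node, dist))
        for p in term[node].parents:
            if p not in visited:
                queue.append((p, dist + 1))
    out.sort(key=lambda x: (x[1], x[0]))
    return out


# ---------------------------------------------------------------------------
# TSV reader / writer


def _split_multi(cell: str) -> list[str]:
    return [v for v in (p.strip() for p in cell.split("|")) if v] if cell else []


def load_terminology(path: str | Path, format: str = "tsv") -> Terminology:
    """Load a terminology from ``path`` in ``tsv`` or ``skos`` format."""
    path = Path(path)
    if format == "tsv":
        return _load_tsv(path)
    if format == "skos":
        return _load_skos(path)
    raise FormatError(f"unknown terminology format: {format!r}")


def _load_tsv(path: Path) -> Terminology:
    with open(path, encoding="utf-8", newline="") as fh:
        return _read_tsv(fh, str(path))


def _read_tsv(fh, name: str) -> Terminology:
    reader = csv.DictReader(fh, delimiter="\t")
    header = reader.fieldnames or []
    for col in REQUIRED_COLUMNS:
        if col not in header:
            raise FormatError(f"{name}: missing required column {col!r}")
    concepts = []
    for row in reader:
        concepts.append(
            Concept(
                id=(row["id"] or "").strip(),
                pref_label=(row["pref_label"] or "").strip(),
                synonyms=_split_multi(row["synonyms"] or ""),
                semantic_types=_split_multi(row["semantic_types"] or ""),
                parents=_split_multi(row["parents"] or ""),
                source=(row["source"] or "").strip(),
            )
        )
    return Terminology(concepts)


def write_terminology_tsv(term: Terminology, path: str | Path) -> None:
    """Write ``term`` back to the canonical TSV layout (round-trip safe)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REQUIRED_COLUMNS)
        for c in term.concepts.values():
            writer.writerow(
                [
                    c.id,
                    c.pref_label,
                    "|".join(c.synonyms),
                    "|".join(c.semantic_types),
                    "|".join(c.parents),
                    c.source,
                ]
            )


# ---------------------------------------------------------------------------
# Minimal SKOS Turtle reader
#
# Supports the subset needed for simple vocabularies: @prefix declarations,
# subject blocks using ';'/',' continuations, IRIs in angle brackets,
# prefixed names, and double-quoted literals with optional language tags.

_TTL_TOKEN = re.compile(
    r"""
      "(?:[^"\\]|\\.)*"(?:@[A-Za-z-]+|\^\^\S+)?   # literal (+ lang tag / datatype)
    | <[^>]*>                                     # IRI
    | @prefix | @base
    | [;,.\[\]]                                   # punctuation
    | [^\s;,.\[\]"<>]+                            # prefixed name / keyword
    """,
    re.VERBOSE,
)

_SKOS_PREDS = {"prefLabel": "pref", "altLabel": "alt", "broader": "broader"}


def _strip_comments(text: str) -> str:
    out_lines = []
    for line in text.splitlines():
        in_str = in_iri = False
        buf = []
        i = 0
        while i < len(line):
            ch = line[i]
            if ch == '"' and not in_iri and (i == 0 or line[i - 1] != "\\"):
                in_str = not in_str
            elif ch == "<" and not in_str:
                in_iri = True
            elif ch == ">" and not in_str:
                in_iri = False
            if ch == "#" and not in_str and not in_iri:
                break
            buf.append(ch)
            i += 1
        out_lines.append("".join(buf))
    return "\n".join(out_lines)


def _resolve(token: str, prefixes: dict[str, str]) -> str:
    if token.startswith("<") and token.endswith(">"):
        return token[1:-1]
    if ":" in token:
        pfx, local = token.split(":", 1)
        if pfx in prefixes:
            return prefixes[pfx] + local
    return token


def _literal_value(token: str) -> str:
    body = token[1:]
    body = body[: body.rindex('"')]
    return body.encode().decode("unicode_escape") if "\\" in body else body


def _load_skos(path: Path) -> Terminology:
    text = _strip_comments(Path(path).read_text(encoding="utf-8"))
    tokens = _TTL_TOKEN.findall(text)
    prefixes: dict[str, str] = {}
    # record per subject: pref label, alt labels, broader ids
    subjects: dict[str, dict[str, list[str]]] = {}
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok in ("@prefix", "@base"):
            if tok == "@prefix" and i + 2 < len(tokens):
                pfx = tokens[i + 1].rstrip(":")
                prefixes[pfx] = _resolve(tokens[i + 2], prefixes)
            while i < len(tokens) and tokens[i] != ".":
                i += 1
            i += 1
            continue
        # subject block
        subject = _resolve(tok, prefixes)
        rec = subjects.setdefault(subject, {"pref": [], "alt": [], "broader": []})
        i += 1
        pred: str | None = None
        while i < len(tokens) and tokens[i] != ".":
            t = tokens[i]
            if t == ";":
                pred = None
            elif t != "," and pred is None:
                pred = t
            else:
                obj = t if t != "," else None
                if obj is not None and pred is not None:
                    local = pred.rsplit(":", 1)[-1].rsplit("#", 1)[-1].rsplit("/", 1)[-1]
                    key = _SKOS_PREDS.get(local)
                    if key == "broader":
                        rec["broader"].append(_resolve(obj, prefixes))
                    elif key and obj.startswith('"'):
                        rec[key].append(_literal_value(obj))
            i += 1
        i += 1  # skip '.'
    concepts = []
    for subj, rec in subjects.items():
        if not rec["pref"] and not rec["alt"]:
            continue
        pref = rec["pref"][0] if rec["pref"] else rec["alt"][0]
        syns = (rec["pref"][1:] if rec["pref"] else []) + [a for a in rec["alt"] if a != pref]
        concepts.append(
            Concept(id=subj, pref_label=pref, synonyms=syns, parents=rec["broader"], source="skos")
        )
    return Terminology(concepts)


def load_terminology_string(text: str, format: str = "tsv") -> Terminology:
    """Convenience: load a terminology from in-memory text (tests, fixtures)."""
    if format == "tsv":
        return _read_tsv(io.StringIO(text), "<string>")
    raise FormatError(f"unsupported in-memory format: {format!r}")
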