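"""Syntactic concept recognition.

Finds every occurrence of a terminology label or synonym in a document at
word boundaries.  Matching is whole-token, case-insensitive and
punctuation-insensitive exactly to the extent :func:`normalize` defines:
a multi-token label must match a contiguous token sequence of the
document (intervening punctuation is invisible, intervening words break
the match).  All matches are returned, including nested and overlapping
occurrences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from ._tokenize import Token, tokenize
from .errors import ConceptLookupError
from .terminology import MATCH_PREF, MATCH_SYN, Terminology, ancestors

NEGATION_DEFAULT = "affirmed"
EXPERIENCER_DEFAULT = "patient"
TEMPORALITY_DEFAULT = "recent"


@dataclass
class Annotation:
    """A recognized concept occurrence.

    Offsets are 0-based code points into the document, end-exclusive
    (BRAT convention); ``document[start:end] == surface`` always holds.
    ``expansion_distance`` is 0 for direct matches and the is_a distance
    for hierarchy-expanded annotations.  ``score`` and the three context
    fields stay ``None`` until the corresponding stage runs.
    """

    concept_id: str
    start: int
    end: int
    surface: str
    match_type: str = MATCH_PREF
    expansion_distance: int = 0
    score: Optional[float] = None
    negation: Optional[str] = None
    experiencer: Optional[str] = None
    temporality: Optional[str] = None
    group: Optional[str] = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def copy(self, **changes) -> "Annotation":
        return replace(self, **changes)


def normalize(text: str) -> list[Token]:
    """Tokenize ``text``: lowercased alphanumeric runs with offsets."""
    return tokenize(text)


class MatchIndex:
    """First-token index over a terminology's normalized labels."""

    def __init__(self, term: Terminology):
        self.terminology = term
        self._by_first: dict[str, list[tuple[tuple[str, ...], str, str]]] = {}
        for label, entries in term.label_index.items():
            toks = tuple(label.split(" "))
            bucket = self._by_first.setdefault(toks[0], [])
            for cid, mtype in entries:
                bucket.append((toks, cid, mtype))
        for bucket in self._by_first.values():
            # longest first so greedy scans can stop early if they want to
            bucket.sort(key=lambda e: (-len(e[0]), e[1], e[2]))

    def candidates(self, first_token: str):
        return self._by_first.get(first_token, ())


def build_index(term: Terminology) -> MatchIndex:
    return MatchIndex(term)


def annotate_direct(doc: str, index: MatchIndex) -> list[Annotation]:
    """All dictionary matches in ``doc``, nested and overlapping included.

    When the same span+concept is reachable through both a preferred
    label and a synonym, a single PREF annotation is kept.  Output is
    sorted by (start, -length, concept_id).
    """
    toks = tokenize(doc)
    words = [t.text for t in toks]
    best: dict[tuple[int, int, str], str] = {}
    for i, w in enumerate(words):
        for label_toks, cid, mtype in index.candidates(w):
            n = len(label_toks)
            if i + n > len(toks):
                continue
            if tuple(words[i : i + n]) != label_toks:
                continue
            span = (toks[i].start, toks[i + n - 1].end)
            key = (span[0], span[1], cid)
            if key not in best or (mtype == MATCH_PREF and best[key] == MATCH_SYN):
                best[key] = mtype
    anns = [
        Annotation(cid, s, e, doc[s:e], match_type=mt)
        for (s, e, cid), mt in best.items()
    ]
    anns.sort(key=lambda a: (a.start, -(a.end - a.start), a.concept_id))
    return anns


def expand_hierarchy(
    anns: list[Annotation], term: Terminology, max_depth: int
) -> list[Annotation]:
    """Add ancestor annotations for every direct match, up to ``max_depth``.

    Each new annotation keeps the span, surface and match type of its
    source and records the is_a distance.  Duplicate (span, concept)
    pairs keep the minimal distance.  ``max_depth == 0`` is the identity.
    """
    for a in anns:
        if a.concept_id not in term:
            raise ConceptLookupError(f"unknown concept id: {a.concept_id!r}")
    if max_depth <= 0:
        return list(anns)
    out = list(anns)
    seen: dict[tuple[int, int, str], int] = {
        (a.start, a.end, a.concept_id): a.expansion_distance for a in anns
    }
    for a in anns:
        if a.expansion_distance != 0:
            continue
        for anc_id, dist in ancestors(term, a.concept_id, max_depth):
            key = (a.start, a.end, anc_id)
            if key in seen and seen[key] <= dist:
                continue
            seen[key] = dist
            out.append(a.copy(concept_id=anc_id, expansion_distance=dist, score=None))
    out.sort(key=lambda x: (x.start, -(x.end - x.start), x.expansion_distance, x.concept_id))
    return out


def longest_only(anns: list[Annotation]) -> list[Annotation]:
    """Drop annotations strictly contained (by span) in a longer one."""
    spans = {(a.start, a.end) for a in anns}
    kept = []
    for a in anns:
        alen = a.end - a.start
        contained = any(
            s <= a.start and a.end <= e and (e - s) > alen for s, e in spans
        )
        if not contained:
            kept.append(a)
    return kept
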