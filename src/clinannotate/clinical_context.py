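"""Clinical context detection: negation, experiencer, temporality.

A rule-based, trigger-scope algorithm operating within sentences.  Every
annotation starts at the defaults (affirmed / patient / recent).  Trigger
phrases open a directional scope: a forward trigger's scope runs from
the token after the trigger to the end of the sentence, cut short at the
first colon or termination term; a backward trigger's scope runs from
the sentence start (or the nearest preceding colon/termination term) to
the token before the trigger.  An annotation falling inside a scope gets
that category's value.  Pseudo phrases suppress the trigger reading of
any phrase they embed (matching is longest-first), and a trigger that
overlaps an annotation's own span never modifies that annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from ._tokenize import Token, token_tuple, tokenize
from .errors import FormatError, IntegrityError
from .recognizer import (
    Annotation,
    EXPERIENCER_DEFAULT,
    NEGATION_DEFAULT,
    TEMPORALITY_DEFAULT,
)

logger = logging.getLogger(__name__)

CATEGORIES = ("negation", "experiencer_other", "historical", "hypothetical")
ROLES = ("trigger", "pseudo", "termination")
DIRECTIONS = ("forward", "backward", "both")

ALL_DIMENSIONS = ("negation", "experiencer", "temporality")

# context category -> (annotation field, value assigned inside scope)
_CATEGORY_EFFECT = {
    "negation": ("negation", "negated"),
    "experiencer_other": ("experiencer", "other"),
    "historical": ("temporality", "historical"),
    "hypothetical": ("temporality", "hypothetical"),
}

_DIMENSION_OF_CATEGORY = {
    "negation": "negation",
    "experiencer_other": "experiencer",
    "historical": "temporality",
    "hypothetical": "temporality",
}

DEFAULT_ABBREVIATIONS = ("dr", "mr", "mrs", "ms", "vs", "e.g", "i.e", "etc", "st")


@dataclass(frozen=True)
class TriggerTerm:
    """A context cue phrase.

    ``direction`` is meaningful for role ``trigger``; pseudo phrases are
    inert superstrings that suppress an embedded trigger; termination
    entries close scopes regardless of category.
    """

    phrase: str
    category: str
    role: str = "trigger"
    direction: str = "forward"

    def __post_init__(self) -> None:
        if not self.phrase.strip():
            raise FormatError("trigger phrase must be non-empty")
        if self.role not in ROLES:
            raise FormatError(f"unknown trigger role {self.role!r}")
        if self.role != "termination" and self.category not in CATEGORIES:
            raise FormatError(f"unknown trigger category {self.category!r}")
        if self.direction not in DIRECTIONS:
            raise FormatError(f"unknown trigger direction {self.direction!r}")

    @property
    def tokens(self) -> tuple[str, ...]:
        return token_tuple(self.phrase)


@dataclass(frozen=True)
class Sentence:
    start: int
    end: int
    text: str


def load_trigger_lexicon(path: str | Path) -> list[TriggerTerm]:
    """Read a pipe-delimited lexicon: ``phrase|category|role|direction``.

    Lines starting with ``#`` and blank lines are skipped; direction
    defaults to forward, role to trigger.
    """
    terms = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("|")]
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected phrase|category[|role[|direction]]")
        phrase, category = parts[0], parts[1]
        role = parts[2] if len(parts) > 2 and parts[2] else "trigger"
        direction = parts[3] if len(parts) > 3 and parts[3] else "forward"
        try:
            terms.append(TriggerTerm(phrase, category, role, direction))
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return terms


def default_lexicon() -> list[TriggerTerm]:
    """The English lexicon shipped with the package."""
    ref = resources.files("clinannotate").joinpath("data/context_triggers.txt")
    with resources.as_file(ref) as path:
        return load_trigger_lexicon(path)


def split_sentences(
    doc: str, abbreviations: Sequence[str] = DEFAULT_ABBREVIATIONS
) -> list[Sentence]:
    """Sentence spans over ``doc``.

    Boundaries: '.', '!', '?' (the punctuation belongs to the preceding
    sentence) and a newline followed by whitespace or end of text.  A '.'
    preceded by a listed abbreviation or flanked by digits does not
    split.  Leading/trailing whitespace is excluded from spans; a
    document without boundaries is one sentence.
    """
    abbrevs = tuple(a.lower() for a in abbreviations)
    boundaries: list[int] = []  # index just past the sentence-final char
    n = len(doc)
    for i, ch in enumerate(doc):
        if ch in "!?":
            boundaries.append(i + 1)
        elif ch == ".":
            if 0 < i < n - 1 and doc[i - 1].isdigit() and doc[i + 1].isdigit():
                continue
            before = doc[:i].lower()
            if any(
                before.endswith(a) and (len(before) == len(a) or not before[-len(a) - 1].isalnum())
                for a in abbrevs
            ):
                continue
            boundaries.append(i + 1)
        elif ch == "\n":
            if i + 1 >= n or doc[i + 1].isspace():
                boundaries.append(i)
    sentences: list[Sentence] = []
    prev = 0
    for b in sorted(set(boundaries)) + [n]:
        if b < prev:
            continue
        seg = doc[prev:b]
        stripped = seg.strip()
        if stripped:
            start = prev + (len(seg) - len(seg.lstrip()))
            end = start + len(stripped)
            sentences.append(Sentence(start, end, doc[start:end]))
        prev = b
    return sentences


@dataclass(frozen=True)
class _Occurrence:
    term: TriggerTerm
    start: int  # char offsets, document coordinates
    end: int
    tok_start: int  # token indices within the sentence
    tok_end: int


class _PhraseIndex:
    """First-token index over lexicon phrases, longest-first."""

    def __init__(self, lexicon: Iterable[TriggerTerm]):
        self._by_first: dict[str, list[tuple[tuple[str, ...], TriggerTerm]]] = {}
        for term in lexicon:
            toks = term.tokens
            if not toks:
                continue
            self._by_first.setdefault(toks[0], []).append((toks, term))
        for bucket in self._by_first.values():
            # longest first; pseudo before trigger at equal length so the
            # suppressing reading wins
            bucket.sort(key=lambda e: (-len(e[0]), 0 if e[1].role == "pseudo" else 1))

    def match_at(self, words: list[str], i: int) -> Optional[tuple[tuple[str, ...], TriggerTerm]]:
        for toks, term in self._by_first.get(words[i], ()):
            if tuple(words[i : i + len(toks)]) == toks:
                return toks, term
        return None


def _find_occurrences(
    sent_tokens: list[Token], index: _PhraseIndex
) -> list[_Occurrence]:
    words = [t.text for t in sent_tokens]
    occs: list[_Occurrence] = []
    i = 0
    while i < len(words):
        hit = index.match_at(words, i)
        if hit is None:
            i += 1
            continue
        toks, term = hit
        j = i + len(toks) - 1
        occs.append(
            _Occurrence(term, sent_tokens[i].start, sent_tokens[j].end, i, j)
        )
        i = j + 1
    return occs


def apply_context(
    doc: str,
    anns: list[Annotation],
    lexicon: Iterable[TriggerTerm],
    dimensions: Sequence[str] = ALL_DIMENSIONS,
    window: Optional[int] = None,
    abbreviations: Sequence[str] = DEFAULT_ABBREVIATIONS,
) -> list[Annotation]:
    """Return copies of ``anns`` with context fields set.

    ``dimensions`` selects which of negation/experiencer/temporality are
    detected; all three fields are always set (undetected dimensions get
    their defaults).  ``window`` optionally caps a scope at that many
    tokens past the trigger instead of running to the sentence end.
    """
    unknown = set(dimensions) - set(ALL_DIMENSIONS)
    if unknown:
        raise FormatError(f"unknown context dimensions: {sorted(unknown)}")
    out = [
        a.copy(
            negation=NEGATION_DEFAULT,
            experiencer=EXPERIENCER_DEFAULT,
            temporality=TEMPORALITY_DEFAULT,
        )
        for a in anns
    ]
    if not out:
        return out
    sentences = split_sentences(doc, abbreviations)
    index = _PhraseIndex(lexicon)
    by_sentence: dict[int, list[Annotation]] = {}
    for a in out:
        placed = False
        for si, s in enumerate(sentences):
            if s.start <= a.start and a.end <= s.end:
                by_sentence.setdefault(si, []).append(a)
                placed = True
                break
        if not placed:
            raise IntegrityError(
                f"annotation span ({a.start}, {a.end}) not covered by any sentence"
            )

    for si, sent_anns in by_sentence.items():
        s = sentences[si]
        sent_tokens = [
            Token(t.text, t.start + s.start, t.end + s.start) for t in tokenize(s.text)
        ]
        occs = _find_occurrences(sent_tokens, index)
        colons = [s.start + k for k, ch in enumerate(s.text) if ch == ":"]
        term_stops = [o for o in occs if o.term.role == "termination"]

        for occ in occs:
            if occ.term.role != "trigger":
                continue
            dim = _DIMENSION_OF_CATEGORY[occ.term.category]
            if dim not in dimensions:
                continue
            field_name, value = _CATEGORY_EFFECT[occ.term.category]
            for lo, hi in _scopes(occ, s, sent_tokens, colons, term_stops, window):
                for a in sent_anns:
                    if a.start >= lo and a.end <= hi and not (
                        a.start < occ.end and occ.start < a.end
                    ):
                        current = getattr(a, field_name)
                        # historical wins over hypothetical when both apply
                        if field_name == "temporality" and current == "historical":
                            continue
                        setattr(a, field_name, value)
    return out


def _scopes(
    occ: _Occurrence,
    sentence: Sentence,
    sent_tokens: list[Token],
    colons: list[int],
    term_stops: list[_Occurrence],
    window: Optional[int],
) -> list[tuple[int, int]]:
    """Character ranges covered by a trigger occurrence's scope(s)."""
    scopes = []
    directions = (
        ("forward", "backward") if occ.term.direction == "both" else (occ.term.direction,)
    )
    for direction in directions:
        if direction == "forward":
            lo = occ.end
            hi = sentence.end
            for c in colons:
                if c >= occ.end:
                    hi = min(hi, c)
                    break
            for stop in term_stops:
                if stop.tok_start > occ.tok_end:
                    hi = min(hi, stop.start)
                    break
            if window is not None and occ.tok_end + window < len(sent_tokens):
                hi = min(hi, sent_tokens[occ.tok_end + window].end)
        else:
            hi = occ.start
            lo = sentence.start
            for c in reversed(colons):
                if c < occ.start:
                    lo = max(lo, c + 1)
                    break
            for stop in reversed(term_stops):
                if stop.tok_end < occ.tok_start:
                    lo = max(lo, stop.end)
                    break
            if window is not None and occ.tok_start - window > 0:
                lo = max(lo, sent_tokens[occ.tok_start - window - 1].end)
        if lo < hi:
            scopes.append((lo, hi))
    return scopes
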