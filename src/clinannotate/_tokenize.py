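"""Shared text normalization.

A token is a maximal run of Unicode letters or digits (underscore excluded),
lowercased.  Offsets are 0-based code-point positions into the original
string, end-exclusive.  Hyphens and apostrophes are token separators, so
"non-small" yields two tokens.
"""

from __future__ import annotations

import re
from typing import NamedTuple

# \w minus underscore: Unicode letters, digits and marks.
_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


class Token(NamedTuple):
    text: str
    start: int
    end: int


def tokenize(text: str) -> list[Token]:
    """Lowercased alphanumeric tokens with their original offsets."""
    return [Token(m.group().lower(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def normalize_label(text: str) -> str:
    """Canonical single-spaced lowercase form of a label or phrase."""
    return " ".join(t.text for t in tokenize(text))


def token_tuple(text: str) -> tuple[str, ...]:
    return tuple(t.text for t in tokenize(text))
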