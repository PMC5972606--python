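"""Semantic-type to semantic-group mapping and group-based filtering.

The mapping table is data, not code: a pipe-delimited file in the NLM
SemGroups layout (``GroupAbbrev|GroupName|TypeCode|TypeName``).  A small
default table ships with the package; deployments can drop in the full
NLM file unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Set

from .errors import ConfigurationError, FormatError, ValidationError
from .recognizer import Annotation
from .terminology import Terminology


@dataclass
class SemanticGroupMap:
    type_to_group: dict[str, tuple[str, str]] = field(default_factory=dict)
    group_to_types: dict[str, set[str]] = field(default_factory=dict)

    def add(self, group_abbrev: str, group_name: str, type_code: str) -> None:
        existing = self.type_to_group.get(type_code)
        if existing is not None and existing[0] != group_abbrev:
            raise ValidationError(
                f"type code {type_code} mapped to both {existing[0]} and {group_abbrev}"
            )
        self.type_to_group[type_code] = (group_abbrev, group_name)
        self.group_to_types.setdefault(group_abbrev, set()).add(type_code)

    def group_of(self, type_code: str) -> str | None:
        entry = self.type_to_group.get(type_code)
        return entry[0] if entry else None

    @property
    def groups(self) -> Set[str]:
        return set(self.group_to_types)


def load_semantic_groups(path: str | Path) -> SemanticGroupMap:
    """Parse a SemGroups-layout table; '#' comments and blank lines skipped."""
    gmap = SemanticGroupMap()
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("|")
        if len(parts) < 4 or not all(p.strip() for p in parts[:3]):
            raise FormatError(f"{path}:{lineno}: expected GroupAbbrev|GroupName|TypeCode|TypeName")
        gmap.add(parts[0].strip(), parts[1].strip(), parts[2].strip())
    return gmap


def default_semantic_groups() -> SemanticGroupMap:
    ref = resources.files("clinannotate").joinpath("data/semantic_groups.txt")
    with resources.as_file(ref) as path:
        return load_semantic_groups(path)


def filter_by_group(
    anns: list[Annotation],
    term: Terminology,
    gmap: SemanticGroupMap,
    groups: Iterable[str],
) -> list[Annotation]:
    """Retain annotations whose concept has a type in a requested group.

    Concepts without semantic types are dropped while filtering is
    active; order is preserved.
    """
    wanted = set(groups)
    if not wanted:
        raise ConfigurationError("group filter requires at least one group")
    unknown = wanted - gmap.groups
    if unknown:
        raise ConfigurationError(
            f"unknown semantic groups {sorted(unknown)}; known: {sorted(gmap.groups)}"
        )
    kept = []
    for a in anns:
        types = term[a.concept_id].semantic_types
        if any(gmap.group_of(t) in wanted for t in types):
            kept.append(a)
    return kept


def filter_by_type(
    anns: list[Annotation], term: Terminology, types: Iterable[str]
) -> list[Annotation]:
    """Retain annotations whose concept carries one of the given type codes."""
    wanted = set(types)
    if not wanted:
        raise ConfigurationError("type filter requires at least one type code")
    return [a for a in anns if wanted & set(term[a.concept_id].semantic_types)]
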