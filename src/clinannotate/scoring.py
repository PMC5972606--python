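"""Annotation scoring and score-based filtering.

Three algorithms are available, all operating within one document:

``old``
    match-type weight sums: every annotation of a concept contributes a
    weight (preferred label, synonym, or a distance-decayed weight for
    hierarchy-expanded matches) and the concept's annotations all carry
    the summed total.

``cvalue``
    termhood-weighted: each distinct directly-matched term contributes
    its match-type weight times the term's C-Value, a measure combining
    term length, frequency and the frequencies of longer matched terms
    that nest it.  Longer multi-word terms therefore outscore shorter
    ones at equal frequency.

``cvalueh``
    as ``cvalue``, with hierarchy-expanded annotations additionally
    contributing a distance-decayed weight times the term's C-Value.

Filtering retains annotations by absolute score or by position in the
document's score distribution (nearest-rank percentile by default; a
cumulative-mass reading is available behind ``percentile_basis``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Iterable

from ._tokenize import normalize_label
from .errors import ConfigurationError, StateError
from .recognizer import Annotation
from .terminology import MATCH_PREF

ALGORITHMS = ("old", "cvalue", "cvalueh")


def default_expanded_weight(d: int) -> float:
    return float(max(10 - d, 1))


@dataclass
class ScoreConfig:
    algorithm: str = "cvalue"
    weight_pref: float = 10.0
    weight_syn: float = 8.0
    weight_expanded: Callable[[int], float] = dc_field(default=default_expanded_weight)
    percentile_basis: str = "value"  # "value" (nearest-rank) or "mass"

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(
                f"unknown scoring algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )
        if not (self.weight_pref >= self.weight_syn > 0):
            raise ConfigurationError("weights must satisfy weight_pref >= weight_syn > 0")

    def match_weight(self, ann: Annotation) -> float:
        if ann.expansion_distance > 0:
            return self.weight_expanded(ann.expansion_distance)
        return self.weight_pref if ann.match_type == MATCH_PREF else self.weight_syn


@dataclass
class TermStats:
    """Per-term statistics over one document's direct annotations."""

    term: str
    length_in_words: int
    frequency: int
    nesting_parents: set[str] = dc_field(default_factory=set)


def _is_token_subsequence(inner: tuple[str, ...], outer: tuple[str, ...]) -> bool:
    n, m = len(inner), len(outer)
    if n >= m:
        return False
    return any(outer[i : i + n] == inner for i in range(m - n + 1))


def build_term_stats(anns: Iterable[Annotation]) -> dict[str, TermStats]:
    """Term statistics from a document's direct annotations.

    The term of an annotation is the normalized surface form; frequency
    counts every direct annotation carrying that term, including
    occurrences nested inside longer matched terms (which the recognizer
    reports separately).
    """
    freqs: dict[str, int] = {}
    for a in anns:
        if a.expansion_distance != 0:
            continue
        t = normalize_label(a.surface)
        if t:
            freqs[t] = freqs.get(t, 0) + 1
    stats: dict[str, TermStats] = {}
    tuples = {t: tuple(t.split(" ")) for t in freqs}
    for t, f in freqs.items():
        parents = {
            other
            for other in freqs
            if other != t and _is_token_subsequence(tuples[t], tuples[other])
        }
        stats[t] = TermStats(t, len(tuples[t]), f, parents)
    return stats


def compute_cvalue(stats: dict[str, TermStats]) -> dict[str, float]:
    """C-Value of every term, floored at 0.

    Non-nested term a:  CV(a) = log2(|a|+1) * f(a).
    Nested term a:      CV(a) = log2(|a|+1) * (f(a) - mean of f(b) over
    the matched terms b that nest a), floored at 0.  The +1 offset keeps
    single-word terms at a nonzero length factor.
    """
    out: dict[str, float] = {}
    for t, st in stats.items():
        length_factor = math.log2(st.length_in_words + 1)
        if not st.nesting_parents:
            cv = length_factor * st.frequency
        else:
            mean_parent_freq = sum(stats[p].frequency for p in st.nesting_parents) / len(
                st.nesting_parents
            )
            cv = length_factor * (st.frequency - mean_parent_freq)
        out[t] = max(cv, 0.0)
    return out


def score_annotations(anns: list[Annotation], cfg: ScoreConfig) -> list[Annotation]:
    """Return copies of ``anns`` with scores set.

    Scores attach per concept per document: all annotations of a concept
    carry the concept's total.
    """
    stats = build_term_stats(anns)
    cvalues = compute_cvalue(stats) if cfg.algorithm in ("cvalue", "cvalueh") else {}

    by_concept: dict[str, list[Annotation]] = {}
    for a in anns:
        by_concept.setdefault(a.concept_id, []).append(a)

    totals: dict[str, float] = {}
    for cid, group in by_concept.items():
        if cfg.algorithm == "old":
            total = sum(cfg.match_weight(a) for a in group)
        else:
            # direct annotations: one contribution per distinct term, at the
            # best match-type weight seen for that term
            direct_w: dict[str, float] = {}
            expanded_w: dict[tuple[str, int], float] = {}
            for a in group:
                t = normalize_label(a.surface)
                if not t:
                    continue
                if a.expansion_distance == 0:
                    w = cfg.match_weight(a)
                    direct_w[t] = max(direct_w.get(t, 0.0), w)
                elif cfg.algorithm == "cvalueh":
                    key = (t, a.expansion_distance)
                    expanded_w[key] = cfg.weight_expanded(a.expansion_distance)
            total = sum(w * cvalues.get(t, 0.0) for t, w in direct_w.items())
            total += sum(w * cvalues.get(t, 0.0) for (t, _d), w in expanded_w.items())
        totals[cid] = total

    return [a.copy(score=totals[a.concept_id]) for a in anns]


def nearest_rank_percentile(values: list[float], pct: float) -> float:
    """Nearest-rank percentile: the value at rank ceil(pct/100 * n)."""
    if not values:
        raise ValueError("empty value list")
    ordered = sorted(values)
    rank = max(1, math.ceil(pct / 100.0 * len(ordered)))
    return ordered[rank - 1]


def filter_by_score(
    anns: list[Annotation],
    mode: str,
    threshold: float,
    percentile_basis: str = "value",
) -> list[Annotation]:
    """Retain annotations by absolute score or score-distribution position.

    ``absolute`` keeps scores >= threshold.  ``percentile`` computes the
    threshold-th percentile P of the annotation scores by nearest rank
    and keeps scores >= P; ties at P are all retained.  With
    ``percentile_basis='mass'`` the cut instead keeps the smallest set of
    top-scoring annotations holding at least (100-threshold)% of the
    total score mass.  Order is preserved.
    """
    if mode not in ("absolute", "percentile"):
        raise ConfigurationError(f"unknown filter mode {mode!r}")
    for a in anns:
        if a.score is None:
            raise StateError("annotations must be scored before filtering; run score_annotations")
    if not anns:
        return []
    if mode == "absolute":
        return [a for a in anns if a.score >= threshold]
    if not (0 <= threshold <= 100):
        raise ConfigurationError("percentile threshold must lie in [0, 100]")
    scores = [a.score for a in anns]
    if percentile_basis == "value":
        cut = nearest_rank_percentile(scores, threshold)
    elif percentile_basis == "mass":
        total = sum(scores)
        target = (100.0 - threshold) / 100.0 * total
        acc = 0.0
        cut = max(scores)
        for s in sorted(set(scores), reverse=True):
            cut = s
            acc += sum(v for v in scores if v == s)
            if acc >= target:
                break
    else:
        raise ConfigurationError(f"unknown percentile basis {percentile_basis!r}")
    return [a for a in anns if a.score >= cut]
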