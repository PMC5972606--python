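"""End-to-end annotation pipeline.

Fixed stage order: direct recognition -> hierarchy expansion ->
semantic group/type filter -> clinical context (enabled dimensions
only) -> scoring -> score filter -> longest-only filter.  Disabling a
stage is exactly the identity on the annotation stream, so with every
feature off the pipeline reproduces the plain recognizer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .clinical_context import TriggerTerm, apply_context, default_lexicon, load_trigger_lexicon
from .errors import ClinAnnotateError, ConfigurationError
from .recognizer import annotate_direct, build_index, expand_hierarchy, longest_only
from .scoring import ScoreConfig, filter_by_score, score_annotations
from .semantic_groups import (
    SemanticGroupMap,
    default_semantic_groups,
    filter_by_group,
    filter_by_type,
    load_semantic_groups,
)
from .serialization import ScoredDocument
from .terminology import Terminology, load_terminology

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    terminology_path: Optional[str] = None
    terminology_format: str = "tsv"
    semantic_group_table: Optional[str] = None
    trigger_lexicon_path: Optional[str] = None
    expansion_depth: int = 0
    negation: bool = False
    experiencer: bool = False
    temporality: bool = False
    context_window: Optional[int] = None
    score_algorithm: Optional[str] = None
    score_threshold: Optional[float] = None  # absolute
    confidence_threshold: Optional[float] = None  # percentile, 0..100
    percentile_basis: str = "value"
    semantic_groups: tuple[str, ...] = ()
    semantic_types: tuple[str, ...] = ()
    longest_only: bool = False
    output_format: str = "json"
    seed: int = 0
    log_level: str = "WARNING"

    def __post_init__(self) -> None:
        if self.expansion_depth < 0:
            raise ConfigurationError("expansion depth must be >= 0")
        if self.confidence_threshold is not None and not (
            0 <= self.confidence_threshold <= 100
        ):
            raise ConfigurationError("confidence threshold must lie in [0, 100]")
        if self.score_threshold is not None and self.confidence_threshold is not None:
            raise ConfigurationError(
                "at most one of score_threshold / confidence_threshold may be set"
            )

    @property
    def context_dimensions(self) -> tuple[str, ...]:
        dims = []
        if self.negation:
            dims.append("negation")
        if self.experiencer:
            dims.append("experiencer")
        if self.temporality:
            dims.append("temporality")
        return tuple(dims)


def run_pipeline(
    cfg: PipelineConfig,
    docs: Sequence[tuple[str, str]],
    terminology: Optional[Terminology] = None,
    group_map: Optional[SemanticGroupMap] = None,
    lexicon: Optional[Sequence[TriggerTerm]] = None,
    failures: Optional[list[tuple[str, Exception]]] = None,
) -> list[ScoredDocument]:
    """Run the full chain over ``docs`` (a list of (doc_id, text) pairs).

    A stage error aborts the affected document (recorded in
    ``failures`` if given, logged otherwise); other documents proceed.
    """
    if terminology is None:
        if cfg.terminology_path is None:
            raise ConfigurationError("a terminology (path or object) is required")
        terminology = load_terminology(cfg.terminology_path, cfg.terminology_format)
    if group_map is None and (cfg.semantic_groups or cfg.semantic_group_table):
        group_map = (
            load_semantic_groups(cfg.semantic_group_table)
            if cfg.semantic_group_table
            else default_semantic_groups()
        )
    if lexicon is None and cfg.context_dimensions:
        lexicon = (
            load_trigger_lexicon(cfg.trigger_lexicon_path)
            if cfg.trigger_lexicon_path
            else default_lexicon()
        )

    index = build_index(terminology)
    results: list[ScoredDocument] = []
    for doc_id, text in docs:
        try:
            results.append(
                _run_one(cfg, doc_id, text, index, terminology, group_map, lexicon)
            )
        except ClinAnnotateError as exc:
            logger.error("document %s failed: %s", doc_id, exc)
            if failures is not None:
                failures.append((doc_id, exc))
    return results


def _run_one(cfg, doc_id, text, index, terminology, group_map, lexicon) -> ScoredDocument:
    anns = annotate_direct(text, index)
    logger.info("%s: %d direct annotations", doc_id, len(anns))

    if cfg.expansion_depth > 0:
        anns = expand_hierarchy(anns, terminology, cfg.expansion_depth)
        logger.info("%s: %d after hierarchy expansion", doc_id, len(anns))

    if cfg.semantic_groups:
        anns = filter_by_group(anns, terminology, group_map, cfg.semantic_groups)
        logger.info("%s: %d after group filter", doc_id, len(anns))
    if cfg.semantic_types:
        anns = filter_by_type(anns, terminology, cfg.semantic_types)
        logger.info("%s: %d after type filter", doc_id, len(anns))

    dims = cfg.context_dimensions
    if dims:
        anns = apply_context(text, anns, lexicon, dimensions=dims, window=cfg.context_window)
        logger.info("%s: context applied (%s)", doc_id, ",".join(dims))

    if cfg.score_algorithm:
        anns = score_annotations(
            anns, ScoreConfig(algorithm=cfg.score_algorithm, percentile_basis=cfg.percentile_basis)
        )
        if cfg.score_threshold is not None:
            anns = filter_by_score(anns, "absolute", cfg.score_threshold)
        elif cfg.confidence_threshold is not None:
            anns = filter_by_score(
                anns, "percentile", cfg.confidence_threshold, cfg.percentile_basis
            )
        logger.info("%s: %d after scoring/filtering", doc_id, len(anns))

    if cfg.longest_only:
        anns = longest_only(anns)
        logger.info("%s: %d after longest-only filter", doc_id, len(anns))

    return ScoredDocument(doc_id, text, anns)
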