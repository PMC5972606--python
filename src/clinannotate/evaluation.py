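"""Evaluation of predicted annotations against a gold corpus.

Micro-averaged precision / recall / F1 pooled across documents, plus
accuracy for clinical context dimensions over gold-matched spans.  Gold
matching is exact-span by default ((doc, start, end, concept) tuples,
each gold record matched at most once); partial-overlap credit is
available as a non-default option.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import ConfigurationError, AlignmentError
from .fixtures import GoldCorpus, GoldRecord
from .serialization import ScoredDocument

CONTEXT_DIMENSIONS = ("negation", "experiencer", "temporality")
_DEFAULTS = {"negation": "affirmed", "experiencer": "patient", "temporality": "recent"}


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    accuracy: Optional[float] = None
    per_class: Optional[dict[str, "EvalResult"]] = None

    @property
    def precision(self) -> float:
        return 1.0 if self.tp + self.fp == 0 else self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        return 1.0 if self.tp + self.fn == 0 else self.tp / (self.tp + self.fn)

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 0.0 if p + r == 0 else 2 * p * r / (p + r)

    def as_percent(self) -> dict[str, float]:
        out = {
            "precision": round(100 * self.precision, 1),
            "recall": round(100 * self.recall, 1),
            "f1": round(100 * self.f1, 1),
        }
        if self.accuracy is not None:
            out["accuracy"] = round(100 * self.accuracy, 1)
        return out


def _check_alignment(pred: Sequence[ScoredDocument], gold: GoldCorpus) -> None:
    gold_ids = {d for d, _ in gold.documents}
    unknown = {sd.doc_id for sd in pred} - gold_ids
    if unknown:
        raise AlignmentError(f"predictions reference unknown doc ids: {sorted(unknown)}")


def _span_tuples(pred: Sequence[ScoredDocument]) -> list[tuple[str, int, int, str]]:
    return [
        (sd.doc_id, a.start, a.end, a.concept_id) for sd in pred for a in sd.annotations
    ]


def evaluate(
    pred: Sequence[ScoredDocument],
    gold: GoldCorpus,
    mode: str = "spans",
    partial_overlap: bool = False,
) -> EvalResult:
    """Score predictions against gold.

    ``mode`` is ``spans`` (exact (doc, start, end, concept) matching),
    ``concepts`` (per-document concept-set comparison) or one of the
    context dimensions (accuracy and per-class P/R/F over gold-matched
    spans).
    """
    _check_alignment(pred, gold)
    if mode == "spans":
        if partial_overlap:
            return _evaluate_overlap(pred, gold)
        pred_counts = Counter(_span_tuples(pred))
        gold_counts = Counter((r.doc_id, r.start, r.end, r.concept_id) for r in gold.gold)
        tp = sum(min(pred_counts[k], gold_counts[k]) for k in pred_counts)
        return EvalResult(tp, sum(pred_counts.values()) - tp, sum(gold_counts.values()) - tp)
    if mode == "concepts":
        tp = fp = fn = 0
        gold_by_doc: dict[str, set[str]] = {}
        for r in gold.gold:
            gold_by_doc.setdefault(r.doc_id, set()).add(r.concept_id)
        pred_by_doc = {sd.doc_id: {a.concept_id for a in sd.annotations} for sd in pred}
        for doc_id, _text in gold.documents:
            p = pred_by_doc.get(doc_id, set())
            g = gold_by_doc.get(doc_id, set())
            tp += len(p & g)
            fp += len(p - g)
            fn += len(g - p)
        return EvalResult(tp, fp, fn)
    if mode in CONTEXT_DIMENSIONS:
        return _evaluate_context(pred, gold, mode)
    raise ConfigurationError(f"unknown evaluation mode {mode!r}")


def _evaluate_context(
    pred: Sequence[ScoredDocument], gold: GoldCorpus, dimension: str
) -> EvalResult:
    gold_by_key: dict[tuple, GoldRecord] = {
        (r.doc_id, r.start, r.end, r.concept_id): r for r in gold.gold
    }
    pairs: list[tuple[str, str]] = []  # (gold value, predicted value)
    for sd in pred:
        for a in sd.annotations:
            rec = gold_by_key.get((sd.doc_id, a.start, a.end, a.concept_id))
            if rec is None:
                continue
            gold_value = getattr(rec, dimension)
            pred_value = getattr(a, dimension) or _DEFAULTS[dimension]
            pairs.append((gold_value, pred_value))
    matches = sum(1 for g, p in pairs if g == p)
    accuracy = matches / len(pairs) if pairs else 0.0

    classes = sorted({g for g, _ in pairs} | {p for _, p in pairs})
    per_class = {}
    for cls in classes:
        tp = sum(1 for g, p in pairs if g == cls and p == cls)
        fp = sum(1 for g, p in pairs if g != cls and p == cls)
        fn = sum(1 for g, p in pairs if g == cls and p != cls)
        per_class[cls] = EvalResult(tp, fp, fn)
    # headline counts pool the non-default classes (the detected phenomena)
    non_default = [c for c in classes if c != _DEFAULTS[dimension]]
    tp = sum(per_class[c].tp for c in non_default)
    fp = sum(per_class[c].fp for c in non_default)
    fn = sum(per_class[c].fn for c in non_default)
    return EvalResult(tp, fp, fn, accuracy=accuracy, per_class=per_class)


def _evaluate_overlap(pred: Sequence[ScoredDocument], gold: GoldCorpus) -> EvalResult:
    """Maximum bipartite matching with overlap+same-concept edges."""
    preds = _span_tuples(pred)
    golds = [(r.doc_id, r.start, r.end, r.concept_id) for r in gold.gold]
    edges: dict[int, list[int]] = {}
    for i, (pd, ps, pe, pc) in enumerate(preds):
        for j, (gd, gs, ge, gc) in enumerate(golds):
            if pd == gd and pc == gc and ps < ge and gs < pe:
                edges.setdefault(i, []).append(j)
    match_of_gold: dict[int, int] = {}

    def try_assign(i: int, seen: set[int]) -> bool:
        for j in edges.get(i, ()):
            if j in seen:
                continue
            seen.add(j)
            if j not in match_of_gold or try_assign(match_of_gold[j], seen):
                match_of_gold[j] = i
                return True
        return False

    tp = sum(1 for i in range(len(preds)) if try_assign(i, set()))
    return EvalResult(tp, len(preds) - tp, len(golds) - tp)
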