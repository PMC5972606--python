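import random

import pytest

from clinannotate.errors import AlignmentError, GenerationError
from clinannotate.evaluation import evaluate
from clinannotate.fixtures import (
    CorpusParams,
    GoldCorpus,
    GoldRecord,
    generate_corpus,
    gold_to_scored_documents,
    read_gold_brat,
    write_gold_brat,
)
from clinannotate.pipeline import PipelineConfig, run_pipeline
from clinannotate.recognizer import Annotation
from clinannotate.serialization import ScoredDocument
from oracles import exhaustive_span_match


class TestGenerateCorpus:
    def test_gold_count_and_defaults(self):
        params = CorpusParams(n_concepts=5, n_notes=10, mentions_per_note=2)
        term, corpus = generate_corpus(params, seed=1)
        assert len(corpus.gold) == 20
        assert len(term) == 5
        for r in corpus.gold:
            assert (r.negation, r.experiencer, r.temporality) == ("affirmed", "patient", "recent")

    def test_span_fidelity(self):
        term, corpus = generate_corpus(CorpusParams(n_notes=5, p_negation=0.5), seed=3)
        for r in corpus.gold:
            assert corpus.text_of(r.doc_id)[r.start : r.end] == term[r.concept_id].pref_label

    def test_same_seed_reproducible(self):
        params = CorpusParams(p_negation=0.3, p_experiencer=0.2, distractor_rate=0.4)
        t1, c1 = generate_corpus(params, seed=42)
        t2, c2 = generate_corpus(params, seed=42)
        assert c1.documents == c2.documents
        assert c1.gold == c2.gold
        assert t1.concepts == t2.concepts

    def test_different_seed_differs(self):
        _, c1 = generate_corpus(CorpusParams(), seed=1)
        _, c2 = generate_corpus(CorpusParams(), seed=2)
        assert c1.documents != c2.documents

    def test_full_negation_wrap(self):
        _, corpus = generate_corpus(CorpusParams(p_negation=1.0), seed=5)
        assert all(r.negation == "negated" for r in corpus.gold)

    def test_pool_too_small(self):
        with pytest.raises(GenerationError, match="pool"):
            generate_corpus(CorpusParams(n_concepts=50, pool_size=20, min_label_tokens=3), seed=1)

    def test_brat_round_trip_via_readers(self, tmp_path):
        _, corpus = generate_corpus(CorpusParams(n_notes=3, p_negation=0.5), seed=9)
        write_gold_brat(corpus, tmp_path)
        docs = read_gold_brat(tmp_path)
        assert len(docs) == 3
        by_id = {sd.doc_id: sd for sd in docs}
        for r in corpus.gold:
            sd = by_id[r.doc_id]
            assert any(
                (a.start, a.end, a.concept_id, a.negation) == (r.start, r.end, r.concept_id, r.negation)
                for a in sd.annotations
            )


class TestEvaluate:
    def _mini_gold(self):
        return GoldCorpus(
            documents=[("d1", "x" * 50)],
            gold=[GoldRecord("d1", 0, 5, "C1"), GoldRecord("d1", 10, 15, "C2")],
        )

    def _pred(self, tuples):
        return [
            ScoredDocument(
                "d1", "x" * 50, [Annotation(cid, s, e, "x" * (e - s)) for (s, e, cid) in tuples]
            )
        ]

    def test_perfect_prediction(self):
        res = evaluate(self._pred([(0, 5, "C1"), (10, 15, "C2")]), self._mini_gold(), "spans")
        assert (res.precision, res.recall, res.f1) == (1.0, 1.0, 1.0)
        assert res.as_percent() == {"precision": 100.0, "recall": 100.0, "f1": 100.0}

    def test_half_right(self):
        res = evaluate(self._pred([(0, 5, "C1"), (20, 25, "C9")]), self._mini_gold(), "spans")
        assert res.tp == 1 and res.fp == 1 and res.fn == 1
        assert res.precision == 0.5 and res.recall == 0.5 and res.f1 == 0.5

    def test_unknown_doc_id(self):
        pred = [ScoredDocument("dX", "y", [])]
        with pytest.raises(AlignmentError):
            evaluate(pred, self._mini_gold(), "spans")

    def test_concepts_mode(self):
        # same concept set, different spans: concepts mode forgives offsets
        res = evaluate(self._pred([(1, 6, "C1"), (11, 16, "C2")]), self._mini_gold(), "concepts")
        assert res.f1 == 1.0
        res = evaluate(self._pred([(0, 5, "C1"), (11, 16, "C2")]), self._mini_gold(), "spans")
        assert res.tp == 1

    def test_matches_exhaustive_matcher_on_random_sets(self):
        rng = random.Random(13)
        for _ in range(50):
            gold_tuples = [
                ("d1", rng.randrange(5) * 10, rng.randrange(5) * 10 + 5, f"C{rng.randint(1, 3)}")
                for _ in range(rng.randint(0, 20))
            ]
            pred_tuples = [
                ("d1", rng.randrange(5) * 10, rng.randrange(5) * 10 + 5, f"C{rng.randint(1, 3)}")
                for _ in range(rng.randint(0, 20))
            ]
            text = "x" * 60
            gold = GoldCorpus(
                documents=[("d1", text)],
                gold=[GoldRecord(d, s, e, c) for (d, s, e, c) in gold_tuples],
            )
            pred = [
                ScoredDocument(
                    "d1", text, [Annotation(c, s, e, text[s:e]) for (_d, s, e, c) in pred_tuples]
                )
            ]
            res = evaluate(pred, gold, "spans")
            expected_tp = exhaustive_span_match(pred_tuples, gold_tuples)
            assert res.tp == expected_tp
            assert res.fp == len(pred_tuples) - expected_tp
            assert res.fn == len(gold_tuples) - expected_tp

    def test_spurious_predictions_degrade_precision_exactly(self):
        gold = self._mini_gold()
        for k in range(1, 5):
            spurious = [(30 + i, 31 + i, "C9") for i in range(k)]
            res = evaluate(
                self._pred([(0, 5, "C1"), (10, 15, "C2")] + spurious), gold, "spans"
            )
            assert res.precision == pytest.approx(2 / (2 + k))
            assert res.recall == 1.0

    def test_permutation_invariance(self):
        gold = GoldCorpus(
            documents=[("d1", "x" * 20), ("d2", "y" * 20)],
            gold=[GoldRecord("d1", 0, 5, "C1"), GoldRecord("d2", 0, 5, "C2")],
        )
        p1 = ScoredDocument("d1", "x" * 20, [Annotation("C1", 0, 5, "xxxxx")])
        p2 = ScoredDocument("d2", "y" * 20, [Annotation("C2", 0, 5, "yyyyy")])
        a = evaluate([p1, p2], gold, "spans")
        b = evaluate([p2, p1], gold, "spans")
        assert (a.tp, a.fp, a.fn) == (b.tp, b.fp, b.fn)

    def test_partial_overlap_mode(self):
        gold = self._mini_gold()
        res = evaluate(self._pred([(2, 7, "C1")]), gold, "spans", partial_overlap=True)
        assert res.tp == 1
        res = evaluate(self._pred([(2, 7, "C1")]), gold, "spans")
        assert res.tp == 0

    def test_context_dimension_accuracy(self):
        gold = GoldCorpus(
            documents=[("d1", "x" * 30)],
            gold=[
                GoldRecord("d1", 0, 5, "C1", negation="negated"),
                GoldRecord("d1", 10, 15, "C2", negation="affirmed"),
            ],
        )
        pred = [
            ScoredDocument(
                "d1",
                "x" * 30,
                [
                    Annotation("C1", 0, 5, "xxxxx", negation="negated"),
                    Annotation("C2", 10, 15, "xxxxx", negation="negated"),
                ],
            )
        ]
        res = evaluate(pred, gold, "negation")
        assert res.accuracy == 0.5
        assert res.per_class["negated"].tp == 1
        assert res.per_class["negated"].fp == 1


class TestClosedLoop:
    def test_default_pipeline_recovers_gold_exactly(self):
        term, corpus = generate_corpus(CorpusParams(n_concepts=5, n_notes=20), seed=7)
        pred = run_pipeline(PipelineConfig(), corpus.documents, terminology=term)
        res = evaluate(pred, corpus, "spans")
        assert (res.precision, res.recall, res.f1) == (1.0, 1.0, 1.0)

    def test_negation_closed_loop(self):
        term, corpus = generate_corpus(CorpusParams(n_notes=10, p_negation=1.0), seed=8)
        pred = run_pipeline(PipelineConfig(negation=True), corpus.documents, terminology=term)
        res = evaluate(pred, corpus, "negation")
        assert res.accuracy == 1.0

    def test_gold_view_scores_perfectly(self):
        _, corpus = generate_corpus(CorpusParams(n_notes=4, p_experiencer=0.5), seed=11)
        res = evaluate(gold_to_scored_documents(corpus), corpus, "spans")
        assert res.f1 == 1.0
        res = evaluate(gold_to_scored_documents(corpus), corpus, "experiencer")
        assert res.accuracy == 1.0
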