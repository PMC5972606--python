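import math
import random

import pytest

from clinannotate.errors import ConfigurationError, StateError
from clinannotate.recognizer import Annotation, annotate_direct, build_index, expand_hierarchy
from clinannotate.scoring import (
    ScoreConfig,
    TermStats,
    build_term_stats,
    compute_cvalue,
    filter_by_score,
    nearest_rank_percentile,
    score_annotations,
)
from helpers import make_terminology
from oracles import cvalue_oracle


def ann(term_text, start=0, concept="C1", match_type="PREF", dist=0, score=None):
    return Annotation(
        concept, start, start + len(term_text), term_text,
        match_type=match_type, expansion_distance=dist, score=score,
    )


class TestComputeCvalue:
    def test_single_unigram(self):
        stats = {"metastasis": TermStats("metastasis", 1, 1, set())}
        assert compute_cvalue(stats) == {"metastasis": 1.0}  # log2(2) * 1

    def test_nested_term_hand_computed(self):
        stats = {
            "metastatic breast cancer": TermStats("metastatic breast cancer", 3, 1, set()),
            "breast cancer": TermStats("breast cancer", 2, 3, {"metastatic breast cancer"}),
        }
        cv = compute_cvalue(stats)
        assert cv["metastatic breast cancer"] == pytest.approx(math.log2(4) * 1)
        assert cv["breast cancer"] == pytest.approx(math.log2(3) * 2)

    def test_floor_at_zero(self):
        # f(a) equals the mean of the parents' frequencies -> CV = 0
        stats = {
            "a b c": TermStats("a b c", 3, 2, set()),
            "a b": TermStats("a b", 2, 2, {"a b c"}),
        }
        assert compute_cvalue(stats)["a b"] == 0.0

    def test_empty(self):
        assert compute_cvalue({}) == {}

    def test_oracle_equivalence_random_term_sets(self):
        rng = random.Random(11)
        vocab = [f"t{i}" for i in range(6)]
        for _ in range(100):
            n_terms = rng.randint(1, 15)
            freqs = {}
            while len(freqs) < n_terms:
                t = " ".join(rng.choice(vocab) for _ in range(rng.randint(1, 4)))
                freqs.setdefault(t, rng.randint(1, 9))
            stats = {
                t: TermStats(
                    t,
                    len(t.split()),
                    f,
                    {
                        o
                        for o in freqs
                        if o != t
                        and len(o.split()) > len(t.split())
                        and any(
                            o.split()[i : i + len(t.split())] == t.split()
                            for i in range(len(o.split()) - len(t.split()) + 1)
                        )
                    },
                )
                for t, f in freqs.items()
            }
            got = compute_cvalue(stats)
            expected = cvalue_oracle(freqs)
            assert got.keys() == expected.keys()
            for t in got:
                assert got[t] == pytest.approx(expected[t])


class TestBuildTermStats:
    def test_frequency_counts_nested_occurrences(self):
        term = make_terminology(
            [("C1", "breast cancer", [], [], []), ("C2", "cancer", [], [], [])]
        )
        anns = annotate_direct("breast cancer and more cancer", build_index(term))
        stats = build_term_stats(anns)
        assert stats["cancer"].frequency == 2  # nested + free-standing
        assert stats["breast cancer"].frequency == 1
        assert stats["cancer"].nesting_parents == {"breast cancer"}
        assert stats["breast cancer"].nesting_parents == set()


class TestScoreAnnotations:
    def test_old_single_pref_match(self):
        scored = score_annotations([ann("fever")], ScoreConfig(algorithm="old"))
        assert scored[0].score == 10.0

    def test_old_additivity_under_duplication(self):
        anns = [ann("fever"), ann("chills", start=10, concept="C2", match_type="SYN")]
        once = score_annotations(anns, ScoreConfig(algorithm="old"))
        twice = score_annotations(anns + [a.copy() for a in anns], ScoreConfig(algorithm="old"))
        for a1, a2 in zip(once, twice):
            assert a2.score == pytest.approx(2 * a1.score)

    def test_cvalue_single_pref_two_word_term(self):
        scored = score_annotations([ann("breast cancer")], ScoreConfig(algorithm="cvalue"))
        assert scored[0].score == pytest.approx(10 * math.log2(3))

    def test_cvalue_favours_longer_terms(self):
        anns = [ann("breast cancer", concept="C1"), ann("fever", start=20, concept="C2")]
        scored = score_annotations(anns, ScoreConfig(algorithm="cvalue"))
        by_cid = {a.concept_id: a.score for a in scored}
        assert by_cid["C1"] > by_cid["C2"]

    def test_cvalue_ignores_expanded_annotations(self):
        anns = [ann("fever"), ann("fever", concept="C9", dist=1)]
        scored = score_annotations(anns, ScoreConfig(algorithm="cvalue"))
        by_cid = {a.concept_id: a.score for a in scored}
        assert by_cid["C9"] == 0.0
        assert by_cid["C1"] > 0

    def test_cvalueh_adds_expansion_contribution(self):
        term = make_terminology([("C1", "fever", [], [], ["C2"]), ("C2", "symptom", [], [], [])])
        anns = expand_hierarchy(annotate_direct("fever", build_index(term)), term, 1)
        scored = score_annotations(anns, ScoreConfig(algorithm="cvalueh"))
        by_cid = {a.concept_id: a.score for a in scored}
        # CV("fever") = log2(2)*1 = 1; expanded weight at d=1 is 9
        assert by_cid["C1"] == pytest.approx(10.0)
        assert by_cid["C2"] == pytest.approx(9.0)

    def test_all_annotations_of_concept_share_score(self):
        anns = [ann("fever"), ann("fever", start=10)]
        scored = score_annotations(anns, ScoreConfig(algorithm="cvalue"))
        assert scored[0].score == scored[1].score

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ConfigurationError):
            ScoreConfig(algorithm="tfidf")

    def test_monotonic_in_word_count(self):
        # fixed frequency and match type: longer terms never score lower
        rng = random.Random(3)
        for _ in range(100):
            n_short = rng.randint(1, 3)
            n_long = n_short + rng.randint(1, 3)
            short = " ".join(f"s{i}" for i in range(n_short))
            long = " ".join(f"l{i}" for i in range(n_long))
            f = rng.randint(1, 5)
            anns = []
            for k in range(f):
                anns.append(ann(short, start=k * 100, concept="CS"))
                anns.append(ann(long, start=k * 100 + 50, concept="CL"))
            scored = score_annotations(anns, ScoreConfig(algorithm="cvalue"))
            by_cid = {a.concept_id: a.score for a in scored}
            assert by_cid["CL"] > by_cid["CS"]


class TestFilterByScore:
    def make_scored(self, scores):
        return [ann(f"t{i}", start=i * 10, concept=f"C{i}", score=s) for i, s in enumerate(scores)]

    def test_percentile_90_nearest_rank(self):
        # nearest rank: ceil(0.9 * 5) = 5th smallest of [1,1,3,5,10] -> 10
        anns = self.make_scored([10, 5, 3, 1, 1])
        kept = filter_by_score(anns, "percentile", 90)
        assert [a.score for a in kept] == [10]

    def test_absolute_zero_identity(self):
        anns = self.make_scored([10, 5, 3, 1, 1])
        assert filter_by_score(anns, "absolute", 0) == anns

    def test_percentile_zero_identity(self):
        anns = self.make_scored([10, 5, 3, 1, 1])
        assert filter_by_score(anns, "percentile", 0) == anns

    def test_ties_at_cut_all_retained(self):
        anns = self.make_scored([4.0, 4.0, 4.0])
        assert filter_by_score(anns, "percentile", 90) == anns

    def test_monotone_shrinkage(self):
        anns = self.make_scored([10, 7, 5, 3, 2, 1])
        sizes = [len(filter_by_score(anns, "percentile", p)) for p in (0, 25, 50, 75, 90, 100)]
        assert sizes == sorted(sizes, reverse=True)

    def test_unscored_raises_state_error(self):
        with pytest.raises(StateError, match="score"):
            filter_by_score([ann("x")], "absolute", 1)

    def test_order_preserved(self):
        anns = self.make_scored([5, 10, 5])
        kept = filter_by_score(anns, "absolute", 5)
        assert kept == anns

    def test_mass_basis_keeps_top_mass(self):
        # total mass 20; threshold 90 keeps the smallest top set holding >= 2
        anns = self.make_scored([10, 5, 3, 1, 1])
        kept = filter_by_score(anns, "percentile", 90, percentile_basis="mass")
        assert [a.score for a in kept] == [10]


class TestNearestRank:
    @pytest.mark.parametrize(
        "values,pct,expected",
        [([1, 1, 3, 5, 10], 90, 10), ([1, 2, 3, 4], 50, 2), ([7], 100, 7), ([3, 9], 0, 3)],
    )
    def test_cases(self, values, pct, expected):
        assert nearest_rank_percentile(values, pct) == expected
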