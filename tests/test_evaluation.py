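import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grangernet import (
    EdgeRanking,
    ParameterError,
    edge_set_accuracy,
    f1_at_k,
    pad_ranking,
    prc,
    pvalue_distribution_report,
    rank_from_coefficients,
    topk_overlap,
)
from grangernet.var_core import CoefficientMatrix


def ranking_of(pairs, scores, p_values=None):
    s, t = zip(*pairs)
    return EdgeRanking.from_arrays(list(s), list(t), list(scores),
                                   p_values=p_values)


GOLD = {("a", "b"), ("b", "c"), ("c", "d")}


class TestEdgeRanking:
    def test_sorted_descending_with_lexicographic_ties(self):
        r = ranking_of(
            [("b", "a"), ("a", "c"), ("a", "b"), ("c", "a")],
            [1.0, 2.0, 1.0, 1.0],
        )
        assert r.entries()[0][:2] == ("a", "c")
        # three tied at 1.0 -> (a,b), (b,a), (c,a)
        assert [e[:2] for e in r.entries()[1:]] == [
            ("a", "b"), ("b", "a"), ("c", "a")
        ]

    def test_self_edges_rejected(self):
        with pytest.raises(ParameterError):
            ranking_of([("a", "a")], [1.0])

    def test_duplicates_rejected(self):
        with pytest.raises(ParameterError):
            ranking_of([("a", "b"), ("a", "b")], [1.0, 0.5])


class TestRankFromCoefficients:
    def _coef(self, B, p, ids):
        return CoefficientMatrix(B=np.asarray(B, float), p=p, gene_ids=ids)

    def test_single_nonzero_entry_ranked_first(self):
        B = np.zeros((2, 2))
        B[0, 1] = 0.8  # g0 -> g1
        r = rank_from_coefficients(self._coef(B, 1, ["g0", "g1"]))
        assert r.entries()[0][:2] == ("g0", "g1")

    @pytest.mark.parametrize(
        "agg,expected", [("max", 0.9), ("sum", 1.1), ("l2", np.hypot(0.2, 0.9))]
    )
    def test_lag_aggregation(self, agg, expected):
        # lag 1 entry 0.2, lag 2 entry -0.9 for pair g0 -> g1
        B = np.zeros((4, 2))
        B[0, 1] = 0.2
        B[2, 1] = -0.9
        r = rank_from_coefficients(self._coef(B, 2, ["g0", "g1"]), aggregation=agg)
        df = r.to_frame().set_index(["source", "target"])
        assert df.loc[("g0", "g1"), "score"] == pytest.approx(expected)

    def test_diagonal_excluded(self):
        B = np.eye(3) * 5.0
        r = rank_from_coefficients(self._coef(B, 1, ["a", "b", "c"]))
        assert len(r) == 6
        assert all(s == 0 for s in r.scores)

    def test_tie_break_stable_across_runs(self):
        B = np.ones((3, 3))
        ids = ["a", "b", "c"]
        r1 = rank_from_coefficients(self._coef(B, 1, ids))
        r2 = rank_from_coefficients(self._coef(B, 1, ids))
        assert [e[:2] for e in r1.entries()] == [e[:2] for e in r2.entries()]


class TestPrc:
    def test_perfect_ranking_has_unit_precision_until_full_recall(self):
        r = ranking_of(
            [("a", "b"), ("b", "c"), ("c", "d"), ("a", "c"), ("d", "a")],
            [5, 4, 3, 2, 1],
        )
        curve = prc(r, GOLD)
        np.testing.assert_allclose(curve.precision[:3], 1.0)
        assert curve.recall[2] == 1.0
        assert curve.auprc == pytest.approx(1.0)

    def test_random_ranking_precision_near_prevalence(self, rng):
        n = 30
        ids = [f"g{i}" for i in range(n)]
        pairs = [(a, b) for a in ids for b in ids if a != b]
        gold = set(pairs[i] for i in rng.choice(len(pairs), 40, replace=False))
        aucs = []
        for _ in range(100):
            scores = rng.random(len(pairs))
            aucs.append(prc(ranking_of(pairs, scores), gold).auprc)
        prevalence = len(gold) / len(pairs)
        assert np.mean(aucs) == pytest.approx(prevalence, rel=0.15)

    def test_no_gold_overlap_zero_auprc(self):
        r = ranking_of([("x", "y"), ("y", "x")], [2, 1])
        with pytest.warns(UserWarning, match="no edges"):
            curve = prc(r, GOLD)
        assert curve.auprc == 0.0

    def test_recall_is_nondecreasing(self, rng):
        n = 10
        ids = [f"g{i}" for i in range(n)]
        pairs = [(a, b) for a in ids for b in ids if a != b]
        gold = {pairs[i] for i in rng.choice(len(pairs), 8, replace=False)}
        curve = prc(ranking_of(pairs, rng.random(len(pairs))), gold)
        assert (np.diff(curve.recall) >= 0).all()

    def test_better_nested_ranking_never_lowers_auprc(self, rng):
        pairs = [("a", "b"), ("b", "c"), ("a", "c"), ("c", "a"),
                 ("c", "d"), ("d", "c")]
        base = prc(ranking_of(pairs, [6, 5, 4, 3, 2, 1]), GOLD).auprc
        # move a gold edge strictly up
        better = prc(ranking_of(pairs, [6, 5, 4, 3, 7, 1]), GOLD).auprc
        assert better >= base


class TestF1AtK:
    def test_top_k_exactly_gold_gives_one(self):
        r = ranking_of(list(GOLD) + [("d", "a")], [3, 3, 3, 1])
        p, rec, f1 = f1_at_k(r, GOLD, 3)
        assert (p, rec, f1) == (1.0, 1.0, 1.0)

    def test_disjoint_top_k_gives_zero(self):
        r = ranking_of([("x", "y"), ("y", "z")], [2, 1])
        assert f1_at_k(r, GOLD, 2) == (0.0, 0.0, 0.0)

    def test_k_equal_gold_size_p_equals_r_equals_f1(self):
        # half the gold set in the top k=|gold|
        r = ranking_of(
            [("a", "b"), ("b", "c"), ("x", "y"), ("y", "x"), ("c", "d")],
            [5, 4, 3, 2, 1],
        )
        gold = GOLD | {("z", "w")}
        p, rec, f1 = f1_at_k(r, gold, 4)
        assert p == rec == f1 == 0.5

    def test_k_beyond_ranking_warns(self):
        r = ranking_of([("a", "b")], [1.0])
        with pytest.warns(UserWarning, match="exceeds"):
            p, rec, f1 = f1_at_k(r, GOLD, 10)
        assert rec == pytest.approx(1 / 3)


class TestTopkOverlap:
    def test_gold_subset_of_topk(self):
        r = ranking_of(list(GOLD), [3, 2, 1])
        with pytest.warns(UserWarning):
            assert topk_overlap(r, GOLD, 10) == 3

    def test_empty_gold_is_zero(self):
        r = ranking_of([("a", "b")], [1.0])
        assert topk_overlap(r, set(), 1) == 0

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_in_k(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"g{i}" for i in range(6)]
        pairs = [(a, b) for a in ids for b in ids if a != b]
        gold = {pairs[i] for i in rng.choice(len(pairs), 5, replace=False)}
        r = ranking_of(pairs, rng.random(len(pairs)))
        counts = [topk_overlap(r, gold, k) for k in range(1, len(pairs) + 1)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestPadRanking:
    def test_pads_to_full_universe_lexicographically(self):
        r = ranking_of([("b", "a")], [2.0])
        padded = pad_ranking(r, ["a", "b", "c"])
        assert len(padded) == 6
        assert padded.entries()[0][:2] == ("b", "a")
        tail = [e[:2] for e in padded.entries()[1:]]
        assert tail == sorted(tail)  # zero-score pad is lexicographic

    def test_unknown_gene_rejected(self):
        r = ranking_of([("q", "a")], [1.0])
        with pytest.raises(ParameterError):
            pad_ranking(r, ["a", "b"])


def test_edge_set_accuracy():
    cand = {("a", "b"), ("b", "a"), ("x", "y"), ("c", "d")}
    assert edge_set_accuracy(cand, GOLD) == pytest.approx(0.5)


class TestPvalueReport:
    def test_identical_scenarios_identical_summaries(self, rng):
        p = rng.random(50)
        rep = pvalue_distribution_report({"s1": p, "s2": p.copy()})
        assert rep.loc["s1"].equals(rep.loc["s2"])

    def test_uniform_pvalues_median_near_half(self, rng):
        rep = pvalue_distribution_report({"u": rng.random(20000)})
        assert rep.loc["u", "median_log10_p"] == pytest.approx(
            np.log10(0.5), abs=0.02
        )

    def test_planted_signal_separates_from_null(self, rng):
        strong = rng.random(200) * 1e-4
        null = rng.random(200)
        rep = pvalue_distribution_report({"gold": strong, "random": null})
        assert (
            rep.loc["gold", "median_log10_p"]
            < rep.loc["random", "median_log10_p"] - 2
        )
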