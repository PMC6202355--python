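import numpy as np
import pytest

from lcpnet import (
    SimilarityChannel,
    aupr,
    benchmark,
    combine_channels,
    evaluate_ranking,
    label_edges,
    precision_curve,
    recall_curve,
)


def channel(values, tag="BP", nodes=("a", "b", "c")):
    return SimilarityChannel.from_edge_values(nodes, values, tag)


class TestSimilarityChannel:
    def test_rejects_asymmetric_matrix(self):
        with pytest.raises(ValueError, match="symmetric"):
            SimilarityChannel(["a", "b"], np.array([[0, 1.0], [0.2, 0]]), "BP")

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            SimilarityChannel(["a", "b"], np.array([[0, 1.5], [1.5, 0]]), "BP")

    def test_rejects_unknown_tag(self):
        with pytest.raises(ValueError, match="tag"):
            SimilarityChannel(["a"], np.zeros((1, 1)), "XX")

    def test_diagonal_ignored_by_validation(self):
        mat = np.array([[7.0, 0.3], [0.3, 7.0]])
        ch = SimilarityChannel(["a", "b"], mat, "CC")
        assert ch.value("a", "b") == 0.3

    def test_csv_round_trip(self, tmp_path):
        ch = channel({("a", "b"): 0.8, ("b", "c"): 0.2})
        p = tmp_path / "ch.csv"
        ch.write_csv(p)
        back = SimilarityChannel.read_csv(p, "BP")
        assert back.nodes == ch.nodes
        np.testing.assert_allclose(back.matrix, ch.matrix)


class TestCombineChannels:
    def test_elementwise_minimum(self):
        bp = channel({("a", "b"): 0.9})
        cc = channel({("a", "b"): 0.4}, tag="CC")
        combined = combine_channels(bp, cc)
        assert combined.value("a", "b") == 0.4
        assert combined.tag == "combined"

    def test_identical_channels_unchanged(self):
        bp = channel({("a", "b"): 0.6, ("b", "c"): 0.6})
        cc = channel({("a", "b"): 0.6, ("b", "c"): 0.6}, tag="CC")
        np.testing.assert_allclose(combine_channels(bp, cc).matrix, bp.matrix)

    def test_mismatched_node_sets_error(self):
        bp = channel({("a", "b"): 0.9})
        cc = channel({("a", "b"): 0.4}, tag="CC", nodes=("a", "b", "d"))
        with pytest.raises(ValueError, match="node sets"):
            combine_channels(bp, cc)


class TestLabelEdges:
    def test_threshold_is_strict(self):
        ch = channel({("a", "b"): 0.5, ("b", "c"): 0.51})
        labels = label_edges(ch, [("a", "b"), ("b", "c")])
        assert labels.tolist() == [False, True]

    def test_all_zero_channel_all_false(self):
        ch = channel({})
        assert not label_edges(ch, [("a", "b"), ("a", "c")]).any()

    def test_missing_edge_named_in_error(self):
        ch = channel({("a", "b"): 0.9})
        with pytest.raises(KeyError, match="zz"):
            label_edges(ch, [("a", "zz")])


class TestPrecisionCurve:
    def test_step_one_hand_values(self):
        ranks, prec, aup = precision_curve([1, 1, 0, 0], step=1)
        assert ranks.tolist() == [1, 2, 3, 4]
        np.testing.assert_allclose(prec, [1, 1, 2 / 3, 1 / 2])
        assert aup == pytest.approx((1 + 1 + 2 / 3 + 1 / 2) / 4)
        assert aup == pytest.approx(0.79167, abs=1e-5)

    def test_perfect_and_null_rankings(self):
        assert precision_curve([True] * 25, step=10)[2] == 1.0
        assert precision_curve([False] * 25, step=10)[2] == 0.0

    def test_final_partial_window_included(self):
        ranks, prec, _ = precision_curve([1, 0, 1, 0, 1], step=2)
        assert ranks.tolist() == [2, 4, 5]
        np.testing.assert_allclose(prec, [1 / 2, 2 / 4, 3 / 5])

    def test_oversized_step_single_point(self, caplog):
        with caplog.at_level("WARNING"):
            ranks, prec, aup = precision_curve([1, 0, 1], step=10)
        assert ranks.tolist() == [3]
        assert aup == pytest.approx(2 / 3)
        assert "step" in caplog.text

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError, match="empty"):
            precision_curve([], step=1)


class TestRecallCurve:
    def test_best_ranking_aur_half(self):
        x, rec, aur, saur = recall_curve([1, 1, 0, 0])
        np.testing.assert_allclose(x, [0.5, 1.0])
        np.testing.assert_allclose(rec, [0.5, 1.0])
        assert aur == pytest.approx(0.5)
        assert saur == pytest.approx(1.0)

    def test_worst_ranking_aur_zero(self):
        _, rec, aur, saur = recall_curve([0, 0, 1, 1])
        np.testing.assert_allclose(rec, [0.0, 0.0])
        assert aur == 0.0 and saur == 0.0

    def test_alternating_hand_trapezoid(self):
        _, rec, aur, saur = recall_curve([1, 0, 1, 0])
        np.testing.assert_allclose(rec, [0.5, 0.5])
        assert aur == pytest.approx(0.375)
        assert saur == pytest.approx(0.75)

    def test_no_positives_errors(self):
        with pytest.raises(ValueError, match="no positive"):
            recall_curve([0, 0, 0])


class TestAupr:
    def test_hand_values(self):
        assert aupr([1, 0, 1]) == pytest.approx((1 + 2 / 3) / 2)
        assert aupr([True] * 5) == 1.0
        assert aupr([0, 1]) == pytest.approx(0.5)

    def test_no_positives_errors(self):
        with pytest.raises(ValueError, match="no positive"):
            aupr([False, False])

    def test_matches_sklearn_average_precision(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(11)
        for _ in range(20):
            labels = rng.random(40) < 0.3
            if not labels.any():
                continue
            scores = -np.arange(40, dtype=float)  # ranking order = given order
            assert aupr(labels) == pytest.approx(
                sklearn_metrics.average_precision_score(labels, scores)
            )


class TestTailInvariances:
    """Appending all-false labels after the last positive."""

    def test_saur_unchanged_by_false_tail(self):
        base = [1, 0, 1, 1, 0]
        extended = base + [0] * 20
        assert recall_curve(extended)[3] == pytest.approx(recall_curve(base)[3])

    def test_aup_changes_with_false_tail(self):
        base = [1, 0, 1, 1, 0]
        extended = base + [0] * 20
        assert precision_curve(extended, 1)[2] < precision_curve(base, 1)[2]


def test_saur_bounds_and_optimality():
    """0 <= sAUR <= 1, with 1 iff all positives precede all negatives."""
    rng = np.random.default_rng(5)
    base = np.array([True] * 6 + [False] * 14)
    for _ in range(200):
        perm = rng.permutation(base)
        saur = recall_curve(perm)[3]
        assert 0.0 <= saur <= 1.0 + 1e-12
        sorted_first = perm[:6].all()
        assert (saur == pytest.approx(1.0)) == sorted_first


def test_aupr_random_ranking_converges_to_prevalence():
    """Random-ranking AUPR matches its exact expectation, which tends to prevalence.

    For P positives uniformly placed among N ranks the expected average
    precision is exactly (P-1)/(N-1) + H_N (N-P) / (N (N-1)): prevalence
    plus a positive O(log N / N) finite-list bias. The shuffle mean must
    sit within 3 standard errors of that expectation, and the bias term
    itself vanishes as the list grows.
    """
    rng = np.random.default_rng(42)
    n, p = 200, 50
    labels = np.array([True] * p + [False] * (n - p))
    harmonic = np.sum(1.0 / np.arange(1, n + 1))
    exact = (p - 1) / (n - 1) + harmonic * (n - p) / (n * (n - 1))
    values = np.array([aupr(rng.permutation(labels)) for _ in range(1000)])
    se = values.std(ddof=1) / np.sqrt(len(values))
    assert abs(values.mean() - exact) <= 3 * se
    # the bias above prevalence decays ~ log(n)/n
    assert 0 < exact - p / n <= 2 * harmonic / n


class TestBenchmark:
    def test_all_true_labels_perfect_row(self, g0):
        truth = np.ones(g0.n_edges, dtype=bool)
        df = benchmark(g0, ["CN"], truth, step=2)
        row = df.loc["CN"]
        assert row["AUP"] == 1.0 and row["sAUR"] == 1.0 and row["AUPR"] == 1.0

    def test_identical_rankings_identical_rows(self, g0):
        # JC and CJC coincide on G0? not guaranteed; use two calls of same method
        truth = np.array([e[0] == "a" for e in g0.edges])
        df1 = benchmark(g0, ["C1star"], truth, step=2)
        df2 = benchmark(g0, ["C1star"], truth, step=2)
        assert df1.equals(df2)

    def test_misaligned_truth_errors(self, g0):
        with pytest.raises(ValueError, match="align"):
            benchmark(g0, ["CN"], [True, False])

    def test_evaluate_ranking_saur_is_twice_aur(self):
        curves = evaluate_ranking([1, 0, 1, 0, 0, 1], step=2)
        assert curves.saur == pytest.approx(2 * curves.aur)
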