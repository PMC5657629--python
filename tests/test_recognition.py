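"""KNN queries, time-label estimation, and vote-based classification."""

import numpy as np
import pytest

from kinaction.recognition import (
    VoteTally,
    classify_segmented,
    classify_stream,
    estimate_time_label,
    knn_query,
)
from kinaction.regularization import TrainingIndex, compute_frame_confidence

from conftest import make_toy_index


def with_confidence(index, value=1.0):
    index.confidence = np.full(len(index), value)
    index.class_weights = {c: 1.0 for c in index.classes}
    return index


class TestKnnQuery:
    def test_exact_match_is_nearest(self):
        index = make_toy_index(seed=1)
        hit = knn_query(index.vectors[17], index, k=1)
        assert hit[0] == 17

    def test_k_equal_to_index_size_returns_everything(self):
        index = make_toy_index(n=20, seed=2)
        out = knn_query(index.vectors[0], index, k=20)
        assert sorted(out.tolist()) == list(range(20))

    def test_matches_bruteforce_with_ties(self):
        index = make_toy_index(n=120, seed=3, grid=0.5)  # snapped -> exact ties
        rng = np.random.default_rng(4)
        for _ in range(30):
            q = np.round(rng.normal(size=10) / 0.5) * 0.5
            got = knn_query(q, index, k=7).tolist()
            expected = sorted(
                range(len(index)),
                key=lambda j: (
                    float(np.linalg.norm(q - index.vectors[j])),
                    index.seq_codes[j],
                    index.time_labels[j],
                ),
            )[:7]
            assert got == expected

    def test_agrees_with_sklearn_on_distinct_points(self):
        from sklearn.neighbors import NearestNeighbors
        index = make_toy_index(n=200, seed=5)
        nn = NearestNeighbors(n_neighbors=9).fit(index.vectors)
        rng = np.random.default_rng(6)
        queries = rng.normal(size=(25, 10))
        _, sk_idx = nn.kneighbors(queries)
        for q, expected in zip(queries, sk_idx):
            got = knn_query(q, index, k=9)
            assert set(got.tolist()) == set(expected.tolist())

    def test_time_window_restricts_and_widens(self):
        index = make_toy_index(n=60, seed=7)
        q = index.vectors[0]
        lo, hi = 10, 12
        out = knn_query(q, index, k=3, time_window=(lo, hi))
        labels = index.time_labels[out]
        inside = (index.time_labels >= lo) & (index.time_labels <= hi)
        if inside.sum() >= 3:
            assert np.all((labels >= lo) & (labels <= hi))
        # a window with no candidates must widen until K are available
        out = knn_query(q, index, k=5, time_window=(1000, 1000))
        assert len(out) == 5

    def test_empty_index_rejected(self):
        index = make_toy_index(n=12, seed=8)
        index.vectors = index.vectors[:0]
        index.class_codes = index.class_codes[:0]
        index.time_labels = index.time_labels[:0]
        index.seq_codes = index.seq_codes[:0]
        with pytest.raises(ValueError):
            knn_query(np.zeros(10), index, k=1)


class TestTimeEstimate:
    def _index_with_labels(self, labels):
        n = len(labels)
        vectors = np.arange(n, dtype=float).reshape(-1, 1) * 0.01
        return TrainingIndex(
            vectors=vectors,
            class_codes=np.zeros(n, int),
            time_labels=np.asarray(labels),
            seq_codes=np.arange(n) % 3,
            classes=("a",),
            source_ids=("s0", "s1", "s2"),
        )

    def test_k1_returns_nearest_label(self):
        index = self._index_with_labels([7, 20, 33])
        est = estimate_time_label(index.vectors[1], index, k=1)
        assert est.t_i == 20

    def test_mode_of_neighbour_labels(self):
        index = self._index_with_labels([10, 11, 10, 40, 10])
        est = estimate_time_label(np.array([0.02]), index, k=5, bin_width=1)
        assert est.t_i == 10

    def test_tie_breaks_to_smaller_label(self):
        index = self._index_with_labels([4, 4, 9, 9])
        est = estimate_time_label(np.array([0.015]), index, k=4)
        assert est.t_i == 4

    def test_benchmark_estimates_near_ground_truth(self, benchmark_index, benchmark_split):
        """Median |T_i - true label| over cross-subject test frames is small."""
        from kinaction.config import PipelineConfig
        from kinaction.evaluation import describe_test_sequence
        from kinaction.recognition import estimate_time_labels
        cfg = PipelineConfig()
        _, test = benchmark_split
        errors = []
        for seq in test[:10]:
            ds = describe_test_sequence(seq, cfg)
            est = estimate_time_labels(ds.vectors, benchmark_index, k=cfg.k_time)
            errors.extend(np.abs(est - ds.time_labels).tolist())
        assert np.median(errors) <= 3


class TestClassifySegmented:
    def test_single_class_index_always_wins(self):
        index = with_confidence(make_toy_index(n=30, n_classes=1, seed=9))
        label, scores = classify_segmented(index.vectors[:4], index, k=3, w_t=5)
        assert label == "a"
        assert scores["a"] == pytest.approx(1.0)

    def test_unanimous_neighbours_score_one(self):
        # two well-separated classes; query frames sit on class b
        rng = np.random.default_rng(10)
        vec_a = rng.normal(0, 0.1, size=(20, 6))
        vec_b = rng.normal(50, 0.1, size=(20, 6))
        index = TrainingIndex(
            vectors=np.vstack([vec_a, vec_b]),
            class_codes=np.array([0] * 20 + [1] * 20),
            time_labels=np.concatenate([np.arange(20)] * 2),
            seq_codes=np.array([0] * 20 + [1] * 20),
            classes=("a", "b"),
            source_ids=("sa", "sb"),
        )
        with_confidence(index)
        label, scores = classify_segmented(vec_b[:6] + 0.01, index, k=5, w_t=5)
        assert label == "b"
        assert scores["b"] == pytest.approx(1.0)

    def test_permutation_invariance(self):
        index = with_confidence(make_toy_index(n=50, seed=11))
        rng = np.random.default_rng(12)
        frames = rng.normal(size=(12, 10))
        label1, scores1 = classify_segmented(frames, index, k=4, w_t=5)
        perm = rng.permutation(12)
        label2, scores2 = classify_segmented(frames[perm], index, k=4, w_t=5)
        assert label1 == label2
        for c in scores1:
            assert scores1[c] == pytest.approx(scores2[c], abs=1e-12)

    def test_empty_input_rejected(self):
        index = with_confidence(make_toy_index(seed=13))
        with pytest.raises(ValueError):
            classify_segmented(np.empty((0, 10)), index, k=3)


class TestVoteTallyGate:
    def test_decision_requires_both_gates(self):
        tally = VoteTally(classes=("a", "b"), t_th=20, alpha_dec=0.5)
        for _ in range(30):
            tally.update(np.array([0.9, 0.1]))
        label, frac = tally.decide()
        assert label == "a" and frac == pytest.approx(0.9)

    def test_no_decision_before_t_th(self):
        tally = VoteTally(classes=("a", "b"), t_th=20, alpha_dec=0.5)
        for _ in range(20):  # frames_seen == t_th is not enough
            tally.update(np.array([1.0, 0.0]))
        assert tally.decide() is None

    def test_no_decision_below_alpha(self):
        tally = VoteTally(classes=("a", "b"), t_th=5, alpha_dec=0.7)
        for _ in range(10):
            tally.update(np.array([0.6, 0.4]))
        assert tally.decide() is None

    def test_full_reset_clears_totals(self):
        tally = VoteTally(classes=("a", "b"), t_th=1, alpha_dec=0.5)
        tally.update(np.array([1.0, 0.0]))
        tally.reset("full")
        assert tally.frames_seen == 0 and tally.totals.sum() == 0


class TestClassifyStream:
    def _stream_setup(self, seed=14):
        rng = np.random.default_rng(seed)
        vec_a = rng.normal(0, 0.1, size=(40, 6))
        vec_b = rng.normal(30, 0.1, size=(40, 6))
        index = TrainingIndex(
            vectors=np.vstack([vec_a, vec_b]),
            class_codes=np.array([0] * 40 + [1] * 40),
            time_labels=np.concatenate([np.arange(40)] * 2),
            seq_codes=np.array([0] * 40 + [1] * 40),
            classes=("a", "b"),
            source_ids=("sa", "sb"),
        )
        with_confidence(index)
        stream = np.vstack([vec_a + 0.01, vec_b + 0.01])
        return index, stream

    def test_two_actions_emitted_in_order(self):
        index, stream = self._stream_setup()
        result = classify_stream(stream, index, k=5, w_t=5, t_th=15, alpha_dec=0.5)
        labels = [d.label for d in result.decisions]
        assert labels[0] == "a" and labels[-1] == "b"
        assert "b" not in labels[: labels.index("b")]

    def test_gate_monotone_in_alpha(self):
        """Lowering alpha_dec never delays the first decision."""
        index, stream = self._stream_setup()
        frames_of_first = []
        for alpha in (0.9, 0.5, 0.2):
            res = classify_stream(stream, index, k=5, w_t=5, t_th=10, alpha_dec=alpha)
            frames_of_first.append(res.decisions[0].frame if res.decisions else np.inf)
        assert frames_of_first[0] >= frames_of_first[1] >= frames_of_first[2]

    def test_gate_monotone_in_t_th(self):
        """Raising T_th never accelerates the first decision."""
        index, stream = self._stream_setup()
        frames_of_first = []
        for t_th in (5, 15, 30):
            res = classify_stream(stream, index, k=5, w_t=5, t_th=t_th, alpha_dec=0.5)
            frames_of_first.append(res.decisions[0].frame if res.decisions else np.inf)
        assert frames_of_first[0] <= frames_of_first[1] <= frames_of_first[2]

    def test_inactive_frames_cast_no_votes(self):
        index, stream = self._stream_setup()
        mask = np.ones(len(stream), bool)
        mask[:20] = False
        res = classify_stream(stream, index, k=5, w_t=5, t_th=10, alpha_dec=0.5,
                              active_mask=mask)
        assert all(lbl is None for lbl in res.frame_labels[:20])
        assert res.decisions[0].frame >= 20
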