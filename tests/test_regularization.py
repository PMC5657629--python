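"""Motion statistic, onset detection, re-basing, training confidence."""

import warnings

import numpy as np
import pytest

from kinaction.config import PipelineConfig
from kinaction.regularization import (
    TrainingIndex,
    class_balance_weights,
    compute_frame_confidence,
    detect_onset,
    fit_training_index,
    motion_statistic,
    regularize_sequence,
)
from kinaction.skeleton_io import SkeletonSequence
from kinaction.synthetic import default_templates, make_subject, generate_action_sequence

from conftest import make_toy_index


def seq_of(topology, coords):
    return SkeletonSequence(coords=np.asarray(coords, float), topology=topology)


class TestMotionStatistic:
    def test_constant_frames_give_zero(self, topology):
        coords = np.tile(np.random.default_rng(0).normal(size=(1, 20, 3)), (9, 1, 1))
        prof = motion_statistic(seq_of(topology, coords))
        assert np.allclose(prof.S, 0.0)

    def test_single_joint_ramp_matches_population_variance(self, topology):
        coords = np.zeros((5, 20, 3))
        coords[:, 0, 0] = [0, 1, 2, 3, 4]
        prof = motion_statistic(seq_of(topology, coords), monitored_joints=("hip_center",))
        assert np.allclose(prof.S[2], [2.0, 0.0, 0.0])  # var{0..4} = 2

    def test_mean_over_joints(self, topology):
        coords = np.zeros((5, 20, 3))
        coords[:, 0, 0] = [0, 1, 2, 3, 4]              # window variance 2
        coords[:, 1, 0] = [0, np.sqrt(2) * 1, np.sqrt(2) * 2,
                           np.sqrt(2) * 3, np.sqrt(2) * 4]  # variance 4
        prof = motion_statistic(seq_of(topology, coords),
                                monitored_joints=("hip_center", "spine"))
        assert prof.S[2, 0] == pytest.approx(3.0)

    def test_boundary_frames_copy_nearest_interior(self, topology):
        rng = np.random.default_rng(1)
        prof = motion_statistic(seq_of(topology, rng.normal(size=(9, 20, 3))))
        assert np.array_equal(prof.S[0], prof.S[2])
        assert np.array_equal(prof.S[1], prof.S[2])
        assert np.array_equal(prof.S[-1], prof.S[-3])

    def test_translation_invariance_exact(self, topology):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(11, 20, 3))
        a = motion_statistic(seq_of(topology, coords))
        b = motion_statistic(seq_of(topology, coords + np.array([5.0, -3.0, 11.0])))
        assert np.allclose(a.S, b.S, atol=1e-10)

    def test_scaling_squares_the_statistic(self, topology):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(11, 20, 3))
        s = 1.7
        a = motion_statistic(seq_of(topology, coords))
        b = motion_statistic(seq_of(topology, coords * s))
        assert np.allclose(b.S, s ** 2 * a.S, rtol=1e-9)


class TestDetectOnset:
    def test_pure_jitter_yields_no_onset(self, topology):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            coords = rng.normal(0.0, 1e-3, size=(60, 20, 3))
            prof = motion_statistic(seq_of(topology, coords))
            assert detect_onset(prof, 0.005) is None

    def test_idle_then_motion_recovered_near_truth(self, topology):
        tpl = default_templates()[0]
        for seed in range(10):
            profile = make_subject("s01", 100 + seed)
            seq, gt = generate_action_sequence(tpl, profile, topology,
                                               idle_prefix=30, seed=seed)
            from kinaction.kinematics import gaussian_smooth
            prof = motion_statistic(gaussian_smooth(seq), PipelineConfig().monitored)
            t0 = detect_onset(prof, 0.005)
            assert t0 is not None and abs(t0 - gt.onset) <= 3

    def test_zero_threshold_fires_at_first_interior_frame(self, topology):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(20, 20, 3))
        prof = motion_statistic(seq_of(topology, coords))
        assert detect_onset(prof, 0.0) == prof.window // 2

    def test_noiseless_onset_within_half_window_all_seeds(self, topology):
        # deterministic sequences: detection lands within T//2 of truth always
        tpl = default_templates()[1]
        from kinaction.kinematics import gaussian_smooth
        for seed in range(10):
            profile = make_subject("sx", 200 + seed, noise_sd=0.0)
            seq, gt = generate_action_sequence(tpl, profile, topology,
                                               idle_prefix=25, seed=seed)
            prof = motion_statistic(gaussian_smooth(seq), PipelineConfig().monitored)
            t0 = detect_onset(prof, 0.005)
            assert t0 is not None and abs(t0 - gt.onset) <= 2


class TestRegularize:
    def test_zero_onset_is_identity(self, topology):
        rng = np.random.default_rng(5)
        seq = seq_of(topology, rng.normal(size=(10, 20, 3)))
        out = regularize_sequence(seq, 0)
        assert np.array_equal(out.coords, seq.coords)

    def test_trims_and_records_mapping(self, topology):
        rng = np.random.default_rng(6)
        seq = seq_of(topology, rng.normal(size=(100, 20, 3)))
        out = regularize_sequence(seq, 27)
        assert out.n_frames == 73
        assert out.metadata["onset_frame"] == 27
        assert np.array_equal(out.coords, seq.coords[27:])

    def test_no_onset_raises(self, topology):
        seq = seq_of(topology, np.zeros((10, 20, 3)))
        with pytest.raises(ValueError, match="onset"):
            regularize_sequence(seq, None)

    def test_training_excludes_onsetless_sequences_with_warning(self, topology):
        tpl = default_templates()[0]
        profile = make_subject("s01", 1)
        good, _ = generate_action_sequence(tpl, profile, topology, idle_prefix=10, seed=0)
        good.sequence_id, good.action_label = "good", "a"
        good2, _ = generate_action_sequence(tpl, profile, topology, idle_prefix=10, seed=1)
        good2.sequence_id, good2.action_label = "good2", "b"
        rng = np.random.default_rng(7)
        idle = SkeletonSequence(
            coords=rng.normal(0, 1e-3, size=(40, 20, 3)), topology=topology,
            sequence_id="idle", action_label="a")
        with pytest.warns(UserWarning, match="idle"):
            index = fit_training_index([good, good2, idle], PipelineConfig(k_confidence=3))
        assert "idle" in index.meta["skipped"]
        assert "idle" not in index.source_ids


class TestFrameConfidence:
    def test_unanimous_neighbours_give_full_confidence(self):
        # 1 query sequence vs 5 identical same-class points elsewhere
        vectors = np.vstack([np.zeros((1, 4)), np.zeros((5, 4)),
                             np.full((5, 4), 10.0)])
        index = TrainingIndex(
            vectors=vectors,
            class_codes=np.array([0] * 6 + [1] * 5),
            time_labels=np.arange(11),
            seq_codes=np.array([0] + [1] * 5 + [2] * 5),
            classes=("a", "b"),
            source_ids=("q", "na", "nb"),
            class_weights={"a": 1.0, "b": 1.0},
        )
        compute_frame_confidence(index, k=5)
        assert index.confidence[0] == pytest.approx(1.0)

    def test_partial_agreement_fraction(self):
        # K=4: 3 of class a, then class-b points, query of class a
        vectors = np.vstack([np.zeros((1, 3)),
                             np.full((3, 3), 0.1),
                             np.full((2, 3), 0.2),
                             np.full((3, 3), 9.0)])
        index = TrainingIndex(
            vectors=vectors,
            class_codes=np.array([0, 0, 0, 0, 1, 1, 1, 1, 1]),
            time_labels=np.arange(9),
            seq_codes=np.array([0, 1, 1, 1, 2, 2, 3, 3, 3]),
            classes=("a", "b"),
            source_ids=("q", "s1", "s2", "s3"),
            class_weights={"a": 1.0, "b": 1.0},
        )
        compute_frame_confidence(index, k=4)
        assert index.confidence[0] == pytest.approx(0.75)

    def test_matches_bruteforce_oracle_on_toy_set(self):
        index = make_toy_index(n=60, n_classes=3, seed=11)
        k = 5
        compute_frame_confidence(index, k=k)
        w = index.class_weights
        for q in range(60):
            pool = [j for j in range(60) if index.seq_codes[j] != index.seq_codes[q]]
            ranked = sorted(
                pool,
                key=lambda j: (
                    float(np.linalg.norm(index.vectors[q] - index.vectors[j])),
                    index.seq_codes[j],
                    index.time_labels[j],
                ),
            )[:k]
            k_t = sum(index.class_codes[j] == index.class_codes[q] for j in ranked)
            expected = w[index.classes[index.class_codes[q]]] * k_t / k
            assert index.confidence[q] == pytest.approx(expected)

    def test_bounded_by_class_weight(self):
        index = make_toy_index(n=80, n_classes=4, seed=12)
        compute_frame_confidence(index, k=7)
        wmax = max(index.class_weights.values())
        assert np.all(index.confidence >= 0)
        assert np.all(index.confidence <= wmax + 1e-12)

    def test_oversized_k_rejected(self):
        index = make_toy_index(n=10, n_seqs=2, seed=13)
        with pytest.raises(ValueError):
            compute_frame_confidence(index, k=9)

    def test_balanced_classes_weight_one(self):
        labels = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10, dtype=object)
        w = class_balance_weights(labels)
        assert all(v == pytest.approx(1.0) for v in w.values())

    def test_inverse_frequency_weighting(self):
        labels = np.array(["a"] * 30 + ["b"] * 10, dtype=object)
        w = class_balance_weights(labels)
        assert w["a"] == pytest.approx(40 / (2 * 30))
        assert w["b"] == pytest.approx(40 / (2 * 10))


class TestConfidenceStructure:
    def test_shared_start_scores_below_mid_action(self, benchmark_index):
        """Frames in the class-shared starting style earn less confidence
        than class-distinctive mid-action frames."""
        idx = benchmark_index
        early = idx.confidence[idx.time_labels <= 4]
        mid = idx.confidence[(idx.time_labels >= 15) & (idx.time_labels <= 40)]
        assert early.mean() < mid.mean()
        assert mid.mean() > 0.99
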