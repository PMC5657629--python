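"""Cross-subject evaluation protocols and reporting.

Models are always trained on one side of a subject partition and scored
on the other — never split by sequence, so no performer appears on both
sides.  Segmented evaluation classifies each test sequence in isolation;
unsegmented evaluation concatenates test sequences into a stream and
scores both the emitted decisions per segment and the per-frame
instantaneous labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .kinematics import build_descriptor, gaussian_smooth
from .recognition import StreamResult, classify_segmented, classify_stream
from .regularization import (
    TrainingIndex,
    detect_onset,
    fit_training_index,
    motion_statistic,
    regularize_sequence,
)
from .skeleton_io import SkeletonSequence
from .synthetic import StreamTruth, SyntheticDataset

__all__ = [
    "SplitSpec",
    "ConfusionMatrix",
    "SegmentedReport",
    "StreamReport",
    "cross_subject_split",
    "describe_test_sequence",
    "evaluate_segmented",
    "evaluate_stream",
    "threshold_sweep",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    """A named cross-subject partition."""

    train_subjects: frozenset
    test_subjects: frozenset
    protocol: str = "cross-subject"

    def __post_init__(self) -> None:
        if not self.train_subjects or not self.test_subjects:
            raise ValueError("both subject sets must be nonempty")
        if self.train_subjects & self.test_subjects:
            raise ValueError("train and test subjects must be disjoint")


def cross_subject_split(
    dataset: SyntheticDataset, spec: SplitSpec
) -> tuple[list[SkeletonSequence], list[SkeletonSequence]]:
    """Partition a dataset's sequences by performer identity."""
    known = set(dataset.subjects)
    unknown = (set(spec.train_subjects) | set(spec.test_subjects)) - known
    if unknown:
        raise ValueError(f"split references unknown subjects: {sorted(unknown)}")
    train = [s for s in dataset.sequences if s.subject_id in spec.train_subjects]
    test = [s for s in dataset.sequences if s.subject_id in spec.test_subjects]
    return train, test


@dataclass
class ConfusionMatrix:
    classes: tuple[str, ...]
    counts: np.ndarray

    @classmethod
    def from_pairs(cls, y_true, y_pred, classes=None) -> "ConfusionMatrix":
        if classes is None:
            classes = tuple(sorted(set(y_true) | set(y_pred)))
        pos = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[pos[t], pos[p]] += 1
        return cls(classes=tuple(classes), counts=counts)

    @property
    def overall_accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else float("nan")

    @property
    def per_class_accuracy(self) -> dict[str, float]:
        rows = self.counts.sum(axis=1)
        return {
            c: float(self.counts[i, i] / rows[i]) if rows[i] else float("nan")
            for i, c in enumerate(self.classes)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


@dataclass
class SegmentedReport:
    confusion: ConfusionMatrix
    predictions: dict[str, tuple[str, dict[str, float]]]

    @property
    def accuracy(self) -> float:
        return self.confusion.overall_accuracy


@dataclass
class StreamReport:
    segment_confusion: ConfusionMatrix
    frame_accuracy: float
    decisions: StreamResult
    segment_predictions: list[tuple[str, str | None]]  # (true, predicted)
    decision_latencies: list[int] = field(default_factory=list)

    @property
    def segment_accuracy(self) -> float:
        good = sum(1 for t, p in self.segment_predictions if p == t)
        return good / len(self.segment_predictions) if self.segment_predictions else float("nan")


def describe_test_sequence(seq: SkeletonSequence, cfg: PipelineConfig):
    """Smooth and (when an onset is found) trim a test sequence, then
    compute its descriptors.  Onset trimming is unsupervised, so applying
    it on the test side leaks nothing; untrimmed sequences are kept whole."""
    dcfg = cfg.descriptor
    sm = gaussian_smooth(seq, dcfg.smooth_width, dcfg.smooth_sigma)
    prof = motion_statistic(sm, cfg.monitored, cfg.onset_window)
    t0 = detect_onset(prof, cfg.onset_threshold, cfg.onset_rms)
    if t0 is not None and sm.n_frames - t0 >= 5:
        sm = regularize_sequence(sm, t0)
    return build_descriptor(sm, dcfg)


def evaluate_segmented(
    index: TrainingIndex,
    test_sequences: list[SkeletonSequence],
    cfg: PipelineConfig | None = None,
) -> SegmentedReport:
    """Classify each test sequence independently and tabulate a confusion
    matrix (deterministic given model + data)."""
    cfg = cfg or PipelineConfig()
    y_true, y_pred = [], []
    predictions: dict[str, tuple[str, dict[str, float]]] = {}
    for seq in test_sequences:
        ds = describe_test_sequence(seq, cfg)
        label, scores = classify_segmented(
            ds.vectors, index, k=cfg.k_classify, w_t=cfg.voting_halfwidth,
            k_time=cfg.k_time, bin_width=cfg.time_bin_width,
        )
        y_true.append(seq.action_label)
        y_pred.append(label)
        predictions[seq.sequence_id or f"seq{len(predictions)}"] = (label, scores)
    cm = ConfusionMatrix.from_pairs(y_true, y_pred, classes=index.classes)
    return SegmentedReport(confusion=cm, predictions=predictions)


def evaluate_stream(
    index: TrainingIndex,
    stream: SkeletonSequence,
    truth: StreamTruth,
    cfg: PipelineConfig | None = None,
) -> StreamReport:
    """Run the streaming classifier over a concatenated stream.

    Segment score: each ground-truth segment is predicted by the majority
    label of the decisions emitted inside it (``None`` if no decision
    fell there).  Frame score: the per-frame instantaneous vote argmax
    against the owning segment's class, excluding ``w_t`` frames on
    either side of each segment boundary.
    """
    cfg = cfg or PipelineConfig()
    dcfg = cfg.descriptor
    sm = gaussian_smooth(stream, dcfg.smooth_width, dcfg.smooth_sigma)
    ds = build_descriptor(sm, dcfg)
    # the motion statistic also gates the stream: idle frames between
    # actions cast no votes.  Onset detection demands motion in every
    # dimension (a conservative "definitely started"); the idle gate only
    # has to separate stillness (S near the squared noise floor) from any
    # motion at all, so it triggers on any dimension clearing Th.
    prof = motion_statistic(sm, cfg.monitored, cfg.onset_window)
    S = np.sqrt(prof.S) if cfg.onset_rms else prof.S
    active = (S.max(axis=1) > cfg.onset_threshold)[ds.frame_indices]
    result = classify_stream(
        ds.vectors, index, k=cfg.k_classify, w_t=cfg.voting_halfwidth,
        t_th=cfg.t_th, alpha_dec=cfg.alpha_dec, k_time=cfg.k_time,
        bin_width=cfg.time_bin_width, reset=cfg.tally_reset, decay=cfg.tally_decay,
        active_mask=active,
    )
    # map descriptor rows back to stream frames
    frame_of_row = ds.frame_indices
    # segment-level score
    seg_preds: list[tuple[str, str | None]] = []
    latencies: list[int] = []
    for start, end, klass in truth.segments:
        inside = [
            d for d in result.decisions
            if start <= frame_of_row[d.frame] < end
        ]
        if inside:
            labels, counts = np.unique([d.label for d in inside], return_counts=True)
            best = counts.max()
            tied = set(labels[counts == best])
            # majority of emitted decisions; ties go to the most recent one
            # (later decisions have seen more of the action)
            pred = next(d.label for d in reversed(inside) if d.label in tied)
            latencies.append(int(frame_of_row[inside[0].frame] - start))
        else:
            pred = None
        seg_preds.append((klass, pred))
    cm = ConfusionMatrix.from_pairs(
        [t for t, p in seg_preds if p is not None],
        [p for _, p in seg_preds if p is not None],
        classes=index.classes,
    )
    # frame-level score on action frames away from transitions (idle-prefix
    # frames have no action to recognise and are excluded)
    w = cfg.voting_halfwidth
    boundaries = [s for s, _, _ in truth.segments[1:]]
    keep = np.ones(len(frame_of_row), dtype=bool)
    for b in boundaries:
        keep &= np.abs(frame_of_row - b) > w
    true_frame = truth.frame_class[frame_of_row]
    pred_frame_all = np.asarray(result.frame_labels, dtype=object)
    keep &= np.array([c is not None for c in true_frame])
    keep &= np.array([p is not None for p in pred_frame_all])
    pred_frame = np.asarray(result.frame_labels, dtype=object)
    frame_acc = float(np.mean(pred_frame[keep] == true_frame[keep])) if keep.any() else float("nan")
    return StreamReport(
        segment_confusion=cm,
        frame_accuracy=frame_acc,
        decisions=result,
        segment_predictions=seg_preds,
        decision_latencies=latencies,
    )


def leakage_digest(train_sequences: list[SkeletonSequence],
                   cfg: PipelineConfig | None = None) -> str:
    """Digest of a model trained on the given sequences; by construction a
    function of the training side only (the leakage canary re-trains after
    permuting test labels and compares digests)."""
    return fit_training_index(train_sequences, cfg).digest()


def threshold_sweep(
    dataset: SyntheticDataset,
    thresholds,
    cfg: PipelineConfig | None = None,
    split: SplitSpec | None = None,
) -> pd.DataFrame:
    """Retrain and re-evaluate (segmented) for each onset threshold Th.

    Rows: Th, segmented accuracy, number of training sequences excluded
    because no onset cleared Th.  A threshold no sequence clears yields
    NaN accuracy with a warning, mirroring a degenerate Th.
    """
    thresholds = list(thresholds)
    if len(thresholds) < 2:
        raise ValueError("need at least 2 threshold values to sweep")
    cfg = cfg or PipelineConfig()
    if split is None:
        train_seqs, test_seqs = dataset.split_odd_even()
    else:
        train_seqs, test_seqs = cross_subject_split(dataset, split)
    rows = []
    for th in thresholds:
        import dataclasses as _dc
        cfg_th = _dc.replace(cfg, onset_threshold=float(th))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                index = fit_training_index(train_seqs, cfg_th)
            n_excluded = len(index.meta.get("skipped", []))
            acc = evaluate_segmented(index, test_seqs, cfg_th).accuracy
        except ValueError:
            warnings.warn(f"Th={th}: no training sequence cleared the threshold",
                          stacklevel=2)
            acc, n_excluded = float("nan"), len(train_seqs)
        rows.append({"threshold": float(th), "accuracy": acc,
                     "n_train_excluded": n_excluded})
    return pd.DataFrame(rows)
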