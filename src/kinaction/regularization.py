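"""Action-onset detection, time-label re-basing, and training confidence.

Public corpora are irregularly segmented: many sequences open with a long
frozen posture before the action proper starts, and early action frames
look alike across classes.  This module addresses both problems:

* the motion statistic S(t) — the per-dimension variance of the monitored
  joints' coordinates over a T-frame window, averaged over joints — finds
  the first genuinely active frame T_start; frames before it are dropped
  and time labels are re-based so T_start maps to 0;
* every training frame then receives a confidence c(X_t) = w(A) K_t / K,
  where K_t of its K nearest neighbours (drawn from *other* training
  sequences) share its true class A.  Frames whose neighbourhood is mixed
  — idle remnants, shared starting styles — get small confidences and
  correspondingly little say in classification later.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.spatial.distance import cdist

from .config import PipelineConfig
from .kinematics import DescriptorSet, build_descriptor, estimate_bone_lengths, gaussian_smooth
from .skeleton_io import SkeletonSequence

__all__ = [
    "MotionProfile",
    "TrainingIndex",
    "motion_statistic",
    "detect_onset",
    "regularize_sequence",
    "compute_frame_confidence",
    "fit_training_index",
]

logger = logging.getLogger(__name__)


@dataclass
class MotionProfile:
    """Per-frame motion statistic S(t) of one sequence.

    ``S`` has shape (frames, 3): one dispersion value per coordinate
    dimension.  Boundary frames (where the window does not fit) carry the
    nearest interior value.
    """

    S: np.ndarray
    window: int
    n_monitored: int
    threshold: float | None = None
    t_start: int | None = None
    active_mask: np.ndarray | None = None


def motion_statistic(
    seq: SkeletonSequence,
    monitored_joints: tuple[str, ...] | None = None,
    window: int = 5,
) -> MotionProfile:
    """Windowed per-dimension variance of the monitored joints.

    For each interior frame t and dimension d,
    ``S_d(t) = mean_i var(P_{i,d}(t-h) .. P_{i,d}(t+h))`` with h = T//2 —
    the population variance over the window, averaged over monitored
    joints.  Idle, jittering limbs give S near the (squared) sensor noise;
    actual movement gives values orders of magnitude larger.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if seq.n_frames < window:
        raise ValueError(f"need at least {window} frames, got {seq.n_frames}")
    if monitored_joints is None:
        coords = seq.coords
    else:
        idx = [seq.topology.index_of(nm) for nm in monitored_joints]
        coords = seq.coords[:, idx, :]
    F, m, _ = coords.shape
    # centring on the first frame makes the statistic exactly zero on
    # constant input and exactly translation-invariant (variance is
    # shift-invariant; this removes the floating-point residue)
    coords = coords - coords[0:1]
    win = np.lib.stride_tricks.sliding_window_view(coords, window, axis=0)
    # win: (F - T + 1, m, 3, T); population variance over the window axis
    var = win.var(axis=-1)
    S_interior = var.mean(axis=1)  # (F - T + 1, 3)
    h = window // 2
    S = np.empty((F, 3))
    S[h:F - h] = S_interior
    S[:h] = S_interior[0]
    S[F - h:] = S_interior[-1]
    return MotionProfile(S=S, window=window, n_monitored=m)


def detect_onset(
    profile: MotionProfile, threshold: float = 0.005, rms: bool = False
) -> int | None:
    """First frame whose motion statistic clears the threshold in all
    three dimensions; ``None`` when the sequence never becomes active.

    With ``rms=True`` the square root of S is compared instead (for
    thresholds expressed in coordinate rather than squared units).
    """
    S = np.sqrt(profile.S) if rms else profile.S
    active = S.min(axis=1) > threshold
    profile.threshold = threshold
    profile.active_mask = active
    # the first window//2 frames carry copied (not measured) statistics and
    # cannot witness a crossing of their own
    hits = np.flatnonzero(active[profile.window // 2:]) + profile.window // 2
    profile.t_start = int(hits[0]) if len(hits) else None
    return profile.t_start


def regularize_sequence(
    seq: SkeletonSequence, t_start: int | MotionProfile
) -> SkeletonSequence:
    """Drop the idle prefix so the detected onset becomes frame 0.

    The old->new frame mapping offset is recorded in the metadata
    (``onset_frame``).  Raises if no onset was found; callers that train
    on corpora decide whether to exclude such sequences (the default) or
    keep them untrimmed.
    """
    if isinstance(t_start, MotionProfile):
        t_start = t_start.t_start
    if t_start is None:
        raise ValueError("no onset detected; sequence cannot be regularized")
    t_start = int(t_start)
    conf = seq.confidence[t_start:] if seq.confidence is not None else None
    return seq.copy_with(
        coords=seq.coords[t_start:],
        confidence=conf,
        metadata={"onset_frame": t_start},
    )


# ---------------------------------------------------------------------------
# training index
# ---------------------------------------------------------------------------

@dataclass
class TrainingIndex:
    """Labelled, regularized training descriptors plus per-frame confidence.

    ``vectors`` is (N, D); ``class_codes``/``seq_codes`` are integer codes
    into ``classes``/``source_ids`` (both sorted, so codes give the
    deterministic KNN tie-break order); ``time_labels`` are regularized
    frame labels; ``confidence`` is c(X_t); ``class_weights`` maps class
    name to w(A) = N_total / (C * N_A).
    """

    vectors: np.ndarray
    class_codes: np.ndarray
    time_labels: np.ndarray
    seq_codes: np.ndarray
    classes: tuple[str, ...]
    source_ids: tuple[str, ...]
    confidence: np.ndarray | None = None
    class_weights: dict[str, float] = field(default_factory=dict)
    k_confidence: int = 5
    metric: str = "euclidean"
    frame_weights: np.ndarray | None = None  # optional mean sensor confidence
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.ascontiguousarray(self.vectors, dtype=float)
        self.class_codes = np.asarray(self.class_codes, dtype=int)
        self.time_labels = np.asarray(self.time_labels, dtype=int)
        self.seq_codes = np.asarray(self.seq_codes, dtype=int)
        n = len(self.vectors)
        for name, arr in (("class_codes", self.class_codes),
                          ("time_labels", self.time_labels),
                          ("seq_codes", self.seq_codes)):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} descriptors")
        if (self.time_labels < 0).any():
            raise ValueError("time labels must be nonnegative after regularization")

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def class_labels(self) -> np.ndarray:
        return np.asarray(self.classes, dtype=object)[self.class_codes]

    def weight_of(self, code: int) -> float:
        return self.class_weights.get(self.classes[code], 1.0)

    # -- persistence ------------------------------------------------------
    def digest(self) -> str:
        """SHA-256 over every array and parameter that defines the model."""
        h = hashlib.sha256()
        for arr in (self.vectors, self.class_codes, self.time_labels, self.seq_codes):
            h.update(np.ascontiguousarray(arr).tobytes())
        if self.confidence is not None:
            h.update(np.ascontiguousarray(self.confidence).tobytes())
        h.update(json.dumps(
            {"classes": self.classes, "source_ids": self.source_ids,
             "weights": sorted(self.class_weights.items()),
             "k": self.k_confidence, "metric": self.metric},
            sort_keys=True).encode())
        return h.hexdigest()

    def save(self, path: str | Path) -> None:
        """Write an HDF5 bundle plus a JSON sidecar (``<path>.json``)."""
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("vectors", data=self.vectors)
            f.create_dataset("class_codes", data=self.class_codes)
            f.create_dataset("time_labels", data=self.time_labels)
            f.create_dataset("seq_codes", data=self.seq_codes)
            if self.confidence is not None:
                f.create_dataset("confidence", data=self.confidence)
            if self.frame_weights is not None:
                f.create_dataset("frame_weights", data=self.frame_weights)
        sidecar = {
            "classes": list(self.classes),
            "source_ids": list(self.source_ids),
            "class_weights": self.class_weights,
            "k_confidence": self.k_confidence,
            "metric": self.metric,
            "meta": self.meta,
            "digest": self.digest(),
        }
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "TrainingIndex":
        path = Path(path)
        with open(path.with_suffix(path.suffix + ".json")) as fh:
            sidecar = json.load(fh)
        with h5py.File(path, "r") as f:
            kwargs = dict(
                vectors=f["vectors"][()],
                class_codes=f["class_codes"][()],
                time_labels=f["time_labels"][()],
                seq_codes=f["seq_codes"][()],
                confidence=f["confidence"][()] if "confidence" in f else None,
                frame_weights=f["frame_weights"][()] if "frame_weights" in f else None,
            )
        return cls(
            classes=tuple(sidecar["classes"]),
            source_ids=tuple(sidecar["source_ids"]),
            class_weights=sidecar["class_weights"],
            k_confidence=sidecar["k_confidence"],
            metric=sidecar["metric"],
            meta=sidecar.get("meta", {}),
            **kwargs,
        )


def class_balance_weights(class_labels: np.ndarray) -> dict[str, float]:
    """Inverse-frequency weights w(A) = N_total / (C * N_A).

    Balanced corpora get w(A) = 1 for every class; over-represented
    classes are down-weighted so long sequences do not dominate the vote.
    """
    labels, counts = np.unique(np.asarray(class_labels, dtype=object), return_counts=True)
    total = counts.sum()
    C = len(labels)
    return {str(lbl): float(total / (C * cnt)) for lbl, cnt in zip(labels, counts)}


def compute_frame_confidence(index: TrainingIndex, k: int | None = None) -> TrainingIndex:
    """Fill ``index.confidence`` with c(X_t) = w(A) K_t / K.

    Each training frame is treated as unlabelled and classified by its K
    nearest neighbours among frames of *other* training sequences (the
    whole source sequence is excluded so adjacent near-duplicate frames
    cannot vote for themselves).  K_t counts neighbours sharing the true
    class.
    """
    k = k or index.k_confidence
    n = len(index)
    if n < k + 1:
        raise ValueError(f"need more than K={k} descriptors, got {n}")
    if not index.class_weights:
        index.class_weights = class_balance_weights(index.class_labels)
    conf = np.empty(n)
    w = np.array([index.weight_of(c) for c in range(len(index.classes))])
    for sc in np.unique(index.seq_codes):
        q = index.seq_codes == sc
        pool = ~q
        if pool.sum() < k:
            raise ValueError(
                f"sequence {index.source_ids[sc]!r}: only {int(pool.sum())} "
                f"descriptors outside it, need K={k}"
            )
        D = cdist(index.vectors[q], index.vectors[pool], metric=index.metric)
        pool_idx = np.flatnonzero(pool)
        # deterministic tie-break: distance, then sequence code, then label
        order = np.lexsort(
            (index.time_labels[pool][None, :].repeat(D.shape[0], 0),
             index.seq_codes[pool][None, :].repeat(D.shape[0], 0),
             D),
            axis=1,
        )[:, :k]
        neigh_classes = index.class_codes[pool_idx[order]]
        own = index.class_codes[q][:, None]
        k_t = (neigh_classes == own).sum(axis=1)
        conf[q] = w[index.class_codes[q]] * k_t / k
    index.confidence = conf
    index.k_confidence = k
    return index


def fit_training_index(
    sequences: list[SkeletonSequence],
    cfg: PipelineConfig | None = None,
) -> TrainingIndex:
    """The full training pipeline: smooth, find onsets, re-base, describe,
    weight, and score confidences.

    Sequences must carry ``action_label`` and a unique ``sequence_id``.
    Sequences in which no onset is found are excluded with a warning.
    """
    cfg = cfg or PipelineConfig()
    dcfg = cfg.descriptor
    sets: list[DescriptorSet] = []
    skipped: list[str] = []
    for seq in sequences:
        if seq.action_label is None or seq.sequence_id is None:
            raise ValueError("training sequences need action_label and sequence_id")
        sm = gaussian_smooth(seq, dcfg.smooth_width, dcfg.smooth_sigma)
        prof = motion_statistic(sm, cfg.monitored, cfg.onset_window)
        t0 = detect_onset(prof, cfg.onset_threshold, cfg.onset_rms)
        if t0 is None:
            skipped.append(seq.sequence_id)
            warnings.warn(
                f"sequence {seq.sequence_id!r}: no motion onset found; excluded from training",
                stacklevel=2,
            )
            continue
        reg = regularize_sequence(sm, t0)
        if reg.n_frames < 5:
            skipped.append(seq.sequence_id)
            warnings.warn(
                f"sequence {seq.sequence_id!r}: fewer than 5 frames after onset; excluded",
                stacklevel=2,
            )
            continue
        sets.append(build_descriptor(reg, dcfg))
    if not sets:
        raise ValueError("no training sequence survived regularization")

    source_ids = tuple(sorted(ds.source_id for ds in sets))
    classes = tuple(sorted({ds.action_label for ds in sets}))
    sid_code = {s: i for i, s in enumerate(source_ids)}
    cls_code = {c: i for i, c in enumerate(classes)}
    vectors = np.concatenate([ds.vectors for ds in sets])
    time_labels = np.concatenate([ds.time_labels for ds in sets])
    seq_codes = np.concatenate(
        [np.full(len(ds), sid_code[ds.source_id]) for ds in sets]
    )
    class_codes = np.concatenate(
        [np.full(len(ds), cls_code[ds.action_label]) for ds in sets]
    )
    index = TrainingIndex(
        vectors=vectors,
        class_codes=class_codes,
        time_labels=time_labels,
        seq_codes=seq_codes,
        classes=classes,
        source_ids=source_ids,
        k_confidence=cfg.k_confidence,
        metric=cfg.metric,
        meta={"n_sequences": len(sets), "skipped": skipped,
              "config": cfg.to_dict()},
    )
    index.class_weights = class_balance_weights(index.class_labels)
    compute_frame_confidence(index, cfg.k_confidence)
    logger.info(
        "trained index: %d descriptors, %d sequences, %d classes (%d skipped)",
        len(index), len(sets), len(classes), len(skipped),
    )
    return index
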