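"""Time-label estimation and confidence-weighted KNN action voting.

Classification happens frame by frame, so it works identically on
segmented sequences and on unbounded streams:

1. a plain KNN over the whole training index estimates the incoming
   frame's regularized time label T_i (mode of the neighbours' labels,
   binned);
2. a second KNN, restricted to training frames whose labels lie within
   +/- w_t of T_i, casts votes weighted by the training frames'
   confidences c(X);
3. votes accumulate over frames; a segmented sequence takes the argmax of
   the accumulated per-class confidence, while a stream additionally
   gates emission on having seen more than T_th frames with a winning
   vote fraction above alpha_dec, then resets and keeps listening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .regularization import TrainingIndex

__all__ = [
    "TimeEstimate",
    "VoteTally",
    "StreamDecision",
    "StreamResult",
    "knn_query",
    "estimate_time_label",
    "estimate_time_labels",
    "classify_segmented",
    "classify_stream",
]

logger = logging.getLogger(__name__)


@dataclass
class TimeEstimate:
    """Estimated regularized time label of one input frame."""

    t_i: int
    votes: dict[int, int]
    neighbour_labels: np.ndarray


@dataclass
class StreamDecision:
    """One emitted stream decision."""

    frame: int              # stream frame index at which the gate opened
    label: str
    score: float            # winning vote fraction at emission
    frames_in_tally: int
    tally: dict[str, float]


@dataclass
class StreamResult:
    decisions: list[StreamDecision]
    frame_labels: list[str]        # per-frame instantaneous argmax label
    frame_time_estimates: np.ndarray


@dataclass
class VoteTally:
    """Accumulated per-class confidence votes with a decision gate."""

    classes: tuple[str, ...]
    t_th: int = 15
    alpha_dec: float = 0.5
    totals: np.ndarray = field(default=None)  # type: ignore[assignment]
    frames_seen: int = 0
    votes_cast: float = 0.0

    def __post_init__(self) -> None:
        if self.totals is None:
            self.totals = np.zeros(len(self.classes))

    def update(self, per_class: np.ndarray) -> None:
        self.totals = self.totals + per_class
        self.votes_cast += float(per_class.sum())
        self.frames_seen += 1

    def decide(self) -> tuple[str, float] | None:
        """Return (label, fraction) once the gate opens, else ``None``."""
        if self.frames_seen <= self.t_th:
            return None
        total = self.totals.sum()
        if total <= 0:
            return None
        best = int(np.argmax(self.totals))
        frac = float(self.totals[best] / total)
        if frac > self.alpha_dec:
            return self.classes[best], frac
        return None

    def reset(self, mode: str = "full", decay: float = 0.5) -> None:
        if mode == "full":
            self.totals = np.zeros(len(self.classes))
            self.votes_cast = 0.0
        elif mode == "decay":
            self.totals = self.totals * decay
            self.votes_cast *= decay
        else:
            raise ValueError(f"unknown reset mode {mode!r}")
        self.frames_seen = 0


# ---------------------------------------------------------------------------
# KNN core
# ---------------------------------------------------------------------------

def _ranked_order(dist_row: np.ndarray, index: TrainingIndex,
                  subset: np.ndarray | None = None) -> np.ndarray:
    """Indices into the index (or subset positions) sorted by distance with
    the deterministic tie-break (sequence code, then time label)."""
    if subset is None:
        return np.lexsort((index.time_labels, index.seq_codes, dist_row))
    return np.lexsort(
        (index.time_labels[subset], index.seq_codes[subset], dist_row)
    )


def knn_query(
    x: np.ndarray,
    index: TrainingIndex,
    k: int,
    time_window: tuple[int, int] | None = None,
    _dist_row: np.ndarray | None = None,
) -> np.ndarray:
    """Exact K nearest training descriptors to ``x``.

    Ties in distance are broken by (sequence code, time label), so results
    are deterministic.  When ``time_window = (lo, hi)`` is given, only
    training frames with regularized labels in [lo, hi] compete; if fewer
    than K fall inside, the window is widened symmetrically one frame at a
    time until K are available (logged at debug level).

    Returns the positions of the neighbours in the index, nearest first.
    """
    n = len(index)
    if n == 0:
        raise ValueError("empty training index")
    k = min(k, n)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    dist = _dist_row if _dist_row is not None else cdist(x, index.vectors, metric=index.metric)[0]
    if time_window is None:
        return _ranked_order(dist, index)[:k]
    lo, hi = int(time_window[0]), int(time_window[1])
    labels = index.time_labels
    inside = (labels >= lo) & (labels <= hi)
    widened = 0
    while inside.sum() < k:
        lo -= 1
        hi += 1
        widened += 1
        inside = (labels >= lo) & (labels <= hi)
    if widened:
        logger.debug("time window widened by %d frames to [%d, %d]", widened, lo, hi)
    sub = np.flatnonzero(inside)
    order = _ranked_order(dist[sub], index, subset=sub)
    return sub[order[:k]]


def estimate_time_label(
    x: np.ndarray,
    index: TrainingIndex,
    k: int = 5,
    bin_width: int = 1,
    _dist_row: np.ndarray | None = None,
) -> TimeEstimate:
    """Mode of the K nearest training frames' regularized time labels.

    Labels are binned with width ``bin_width``; the estimate is the centre
    label of the winning bin, with ties resolved toward the smaller label.
    """
    neigh = knn_query(x, index, k, _dist_row=_dist_row)
    labels = index.time_labels[neigh]
    bins = labels // bin_width
    counts: dict[int, int] = {}
    for b in bins.tolist():
        counts[b] = counts.get(b, 0) + 1
    best_bin = min(counts, key=lambda b: (-counts[b], b))
    centre = best_bin * bin_width + bin_width // 2
    return TimeEstimate(t_i=int(centre), votes=counts, neighbour_labels=labels)


def estimate_time_labels(
    vectors: np.ndarray, index: TrainingIndex, k: int = 5, bin_width: int = 1
) -> np.ndarray:
    """Vectorised :func:`estimate_time_label` over the rows of ``vectors``."""
    D = cdist(np.atleast_2d(vectors), index.vectors, metric=index.metric)
    return np.array([
        estimate_time_label(v, index, k, bin_width, _dist_row=D[i]).t_i
        for i, v in enumerate(np.atleast_2d(vectors))
    ])


def _frame_votes(
    dist_row: np.ndarray,
    t_i: int,
    index: TrainingIndex,
    k: int,
    w_t: int,
    weight: float = 1.0,
) -> np.ndarray:
    """Per-class confidence votes cast by one input frame."""
    neigh = knn_query(
        None, index, k, time_window=(t_i - w_t, t_i + w_t), _dist_row=dist_row
    )
    votes = np.zeros(len(index.classes))
    conf = index.confidence if index.confidence is not None else np.ones(len(index))
    np.add.at(votes, index.class_codes[neigh], conf[neigh] * weight)
    return votes


def classify_segmented(
    vectors: np.ndarray,
    index: TrainingIndex,
    k: int = 5,
    w_t: int = 5,
    k_time: int | None = None,
    bin_width: int = 1,
    time_labels: np.ndarray | None = None,
    frame_weights: np.ndarray | None = None,
) -> tuple[str, dict[str, float]]:
    """Classify a segmented sequence of frame descriptors.

    Every frame estimates its time label, gathers its K nearest training
    frames within the +/- w_t voting window, and adds their confidences to
    its class's tally; the argmax class wins (ties toward the first class
    in sorted order) and scores are returned normalised to sum to 1.

    ``time_labels`` overrides the per-frame estimates (used e.g. to study
    sensitivity to estimation errors); ``frame_weights`` optionally scales
    each frame's votes (e.g. by mean sensor confidence).
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if len(vectors) == 0:
        raise ValueError("empty frame list")
    if index.confidence is None:
        raise ValueError("training index has no confidence; run compute_frame_confidence")
    k_time = k_time or k
    D = cdist(vectors, index.vectors, metric=index.metric)
    totals = np.zeros(len(index.classes))
    for i in range(len(vectors)):
        if time_labels is None:
            t_i = estimate_time_label(vectors[i], index, k_time, bin_width, _dist_row=D[i]).t_i
        else:
            t_i = int(time_labels[i])
        wgt = 1.0 if frame_weights is None else float(frame_weights[i])
        totals += _frame_votes(D[i], t_i, index, k, w_t, wgt)
    total = totals.sum()
    scores = totals / total if total > 0 else np.full_like(totals, 1.0 / len(totals))
    best = int(np.argmax(totals))
    return index.classes[best], {c: float(s) for c, s in zip(index.classes, scores)}


def classify_stream(
    vectors,
    index: TrainingIndex,
    k: int = 5,
    w_t: int = 5,
    t_th: int = 15,
    alpha_dec: float = 0.5,
    k_time: int | None = None,
    bin_width: int = 1,
    reset: str = "full",
    decay: float = 0.5,
    frame_weights: np.ndarray | None = None,
    active_mask: np.ndarray | None = None,
    idle_reset_frames: int = 10,
) -> StreamResult:
    """Classify an unsegmented stream of frame descriptors.

    Frames arrive independently — no ordering of their true time labels is
    assumed.  A :class:`VoteTally` accumulates each frame's votes; once
    more than ``t_th`` frames have been tallied and the leading class
    holds more than ``alpha_dec`` of the accumulated confidence, the class
    is emitted and the tally resets (fully, or by exponential ``decay``).
    Per-frame cost is linear in the index size, so the loop is real-time
    for moderate training sets.

    ``active_mask`` marks frames that pass the motion-activity check (the
    same windowed-variance threshold used to find action onsets); inactive
    frames — idle gaps between actions — cast no votes and do not advance
    the decision gate, so the tally is not diluted between actions.  A run
    of ``idle_reset_frames`` consecutive inactive frames is read as a
    boundary between actions and resets the tally, so one action's votes
    do not leak into the next.
    """
    if index.confidence is None:
        raise ValueError("training index has no confidence; run compute_frame_confidence")
    k_time = k_time or k
    vec_arr = np.atleast_2d(np.asarray(vectors, dtype=float))
    D = cdist(vec_arr, index.vectors, metric=index.metric)
    tally = VoteTally(classes=index.classes, t_th=t_th, alpha_dec=alpha_dec)
    decisions: list[StreamDecision] = []
    frame_labels: list[str] = []
    t_est = np.empty(len(vec_arr), dtype=int)
    inactive_run = 0
    for i in range(len(vec_arr)):
        if active_mask is not None and not active_mask[i]:
            t_est[i] = -1
            frame_labels.append(None)
            inactive_run += 1
            if inactive_run == idle_reset_frames:
                tally.reset("full")
            continue
        inactive_run = 0
        t_i = estimate_time_label(vec_arr[i], index, k_time, bin_width, _dist_row=D[i]).t_i
        t_est[i] = t_i
        wgt = 1.0 if frame_weights is None else float(frame_weights[i])
        votes = _frame_votes(D[i], t_i, index, k, w_t, wgt)
        frame_labels.append(index.classes[int(np.argmax(votes))])
        tally.update(votes)
        verdict = tally.decide()
        if verdict is not None:
            label, frac = verdict
            decisions.append(
                StreamDecision(
                    frame=i,
                    label=label,
                    score=frac,
                    frames_in_tally=tally.frames_seen,
                    tally={c: float(v) for c, v in zip(index.classes, tally.totals)},
                )
            )
            tally.reset(reset, decay)
    return StreamResult(decisions=decisions, frame_labels=frame_labels,
                        frame_time_estimates=t_est)
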