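"""The angular spatio-temporal frame descriptor.

Each frame t of a smoothed skeleton sequence is described by

    X_t = [ pose, lambda * omega, epsilon * alpha ]

concatenated over a configurable subset of joints, where

* ``pose``  = eta / L * (p_i - p_hip), the hip-centred pose normalised by
  the subject's hip-segment length L;
* ``omega`` = P'(t) / d_i, a bone-length-normalised ("angular") velocity,
  with P'(t) = P(t+1) - P(t-1);
* ``alpha`` = P''(t) / d_i, the matching angular acceleration, with
  P''(t) = P(t+2) + P(t-2) - 2 P(t).

The differences come from a 5-frame window centred on t, so the descriptor
is local in time; dividing by the subject's own bone lengths d_i and hip
segment L makes it invariant to body size, and hip-centring / differencing
make it invariant to global translation.  Nothing is divided by the frame
period: descriptors from corpora at different frame rates are only
comparable after resampling, which is a configuration concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import convolve1d

from .skeleton_io import SkeletonSequence, SkeletonTopology

__all__ = [
    "DescriptorConfig",
    "FrameDescriptor",
    "DescriptorSet",
    "DEFAULT_SELECTED_JOINTS",
    "gaussian_smooth",
    "select_joints",
    "to_relative_normalized",
    "finite_differences",
    "angular_kinematics",
    "build_descriptor",
    "estimate_bone_lengths",
]

# head + full limbs; shoulders, neck, spine and hips are excluded because
# they barely move relative to the torso and mostly add dimensions.
DEFAULT_SELECTED_JOINTS: tuple[str, ...] = (
    "head",
    "elbow_left", "wrist_left", "hand_left",
    "elbow_right", "wrist_right", "hand_right",
    "knee_left", "ankle_left", "foot_left",
    "knee_right", "ankle_right", "foot_right",
)

#: frames at each end of a sequence whose 5-frame stencil does not fit
EDGE = 2


@dataclass
class DescriptorConfig:
    """Free parameters of the descriptor.

    ``lam`` and ``eps`` weight the velocity and acceleration blocks
    against the pose block; ``eta`` is the dimensionless pose scale
    (absorbed by the KNN distance, so 1.0 by default); ``edge_policy``
    says what happens to the first/last two frames whose stencil does not
    fit: ``"drop"`` discards them, ``"copy"`` duplicates the nearest
    interior kinematics (flagged in the descriptor set).
    """

    lam: float = 0.8
    eps: float = 0.6
    eta: float = 1.0
    selected_joints: tuple[str, ...] = DEFAULT_SELECTED_JOINTS
    smooth_width: int = 5
    smooth_sigma: float = 1.0
    edge_policy: str = "drop"

    def __post_init__(self) -> None:
        if self.lam < 0 or self.eps < 0:
            raise ValueError("lam and eps must be nonnegative")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if not self.selected_joints:
            raise ValueError("selected_joints must be nonempty")
        if self.smooth_width % 2 == 0 or self.smooth_width < 3:
            raise ValueError("smooth_width must be odd and >= 3")
        if self.edge_policy not in ("drop", "copy"):
            raise ValueError("edge_policy must be 'drop' or 'copy'")

    @property
    def n_selected(self) -> int:
        return len(self.selected_joints)

    @property
    def descriptor_dim(self) -> int:
        return 9 * self.n_selected


@dataclass
class FrameDescriptor:
    """One frame's descriptor, exploded into its blocks."""

    pose: np.ndarray        # (m_sel, 3)
    omega: np.ndarray       # (m_sel, 3)
    alpha: np.ndarray       # (m_sel, 3)
    vector: np.ndarray      # (9 * m_sel,)
    time_label: int
    action_label: str | None
    source_id: str | None
    frame_index: int = -1   # index in the source sequence (provenance)


class DescriptorSet:
    """Array-backed collection of frame descriptors for one sequence.

    Indexing yields :class:`FrameDescriptor` views; the underlying matrix
    is ``vectors`` (n_frames_kept x 9 m_sel), ordered [pose | lam*omega |
    eps*alpha] block-major over the selected joints.
    """

    def __init__(
        self,
        vectors: np.ndarray,
        time_labels: np.ndarray,
        frame_indices: np.ndarray,
        config: DescriptorConfig,
        action_label: str | None = None,
        source_id: str | None = None,
        edge_copied: np.ndarray | None = None,
    ) -> None:
        self.vectors = np.asarray(vectors, dtype=float)
        self.time_labels = np.asarray(time_labels, dtype=int)
        self.frame_indices = np.asarray(frame_indices, dtype=int)
        self.config = config
        self.action_label = action_label
        self.source_id = source_id
        self.edge_copied = (
            edge_copied if edge_copied is not None else np.zeros(len(self.vectors), bool)
        )
        if not np.isfinite(self.vectors).all():
            raise ValueError("descriptor vectors contain non-finite entries")

    def __len__(self) -> int:
        return len(self.vectors)

    def __getitem__(self, i: int) -> FrameDescriptor:
        m = self.config.n_selected
        v = self.vectors[i]
        lam = self.config.lam if self.config.lam > 0 else 1.0
        eps = self.config.eps if self.config.eps > 0 else 1.0
        return FrameDescriptor(
            pose=v[: 3 * m].reshape(m, 3),
            omega=v[3 * m: 6 * m].reshape(m, 3) / lam,
            alpha=v[6 * m:].reshape(m, 3) / eps,
            vector=v,
            time_label=int(self.time_labels[i]),
            action_label=self.action_label,
            source_id=self.source_id,
            frame_index=int(self.frame_indices[i]),
        )

    def with_time_labels(self, labels: np.ndarray) -> "DescriptorSet":
        out = DescriptorSet(
            self.vectors, labels, self.frame_indices, self.config,
            self.action_label, self.source_id, self.edge_copied,
        )
        return out


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def gaussian_kernel(width: int = 5, sigma: float = 1.0) -> np.ndarray:
    """Sampled Gaussian taps at integer offsets, normalised to sum to 1."""
    if width % 2 == 0 or width < 3:
        raise ValueError("width must be odd and >= 3")
    half = width // 2
    j = np.arange(-half, half + 1)
    k = np.exp(-(j ** 2) / (2.0 * sigma ** 2))
    return k / k.sum()


def gaussian_smooth(
    seq: SkeletonSequence, width: int = 5, sigma: float = 1.0
) -> SkeletonSequence:
    """Smooth every coordinate channel with a width-tap Gaussian.

    Boundary frames are filtered with the truncated kernel renormalised to
    sum to 1, so constants are preserved everywhere and no frames are lost.
    The causal interpretation of the centred filter entails a group delay
    of ``width // 2`` frames, recorded in the sequence metadata.
    """
    if seq.n_frames < width:
        raise ValueError(f"need at least {width} frames to smooth, got {seq.n_frames}")
    k = gaussian_kernel(width, sigma)
    num = convolve1d(seq.coords, k, axis=0, mode="constant", cval=0.0)
    den = convolve1d(np.ones(seq.n_frames), k, mode="constant", cval=0.0)
    smoothed = num / den[:, None, None]
    return seq.copy_with(
        coords=smoothed,
        metadata={"smoothed": True, "smooth_delay_frames": width // 2,
                  "smooth_width": width, "smooth_sigma": sigma},
    )


# ---------------------------------------------------------------------------
# descriptor building blocks
# ---------------------------------------------------------------------------

def select_joints(seq: SkeletonSequence, names: Sequence[str]) -> SkeletonSequence:
    """Restrict a sequence to the named joints, in the given order."""
    idx = [seq.topology.index_of(nm) for nm in names]
    sub = seq.topology.subset(names)
    conf = seq.confidence[:, idx] if seq.confidence is not None else None
    return seq.copy_with(coords=seq.coords[:, idx, :], topology=sub, confidence=conf)


def to_relative_normalized(
    seq: SkeletonSequence, eta: float = 1.0, hip_segment_length: float | None = None
) -> SkeletonSequence:
    """Centre every frame on the hip and scale by eta / L.

    The hip-centre joint maps exactly to the origin; uniform rescaling of
    the subject (coordinates and L together) leaves the output unchanged.
    """
    L = hip_segment_length if hip_segment_length is not None else seq.topology.hip_segment_length
    if L <= 0:
        raise ValueError("hip segment length must be positive")
    hip = seq.topology.hip_center_index
    if hip < 0:
        raise ValueError("sequence topology has no hip-centre joint")
    rel = (eta / L) * (seq.coords - seq.coords[:, hip:hip + 1, :])
    return seq.copy_with(coords=rel)


def finite_differences(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central differences over the 5-frame stencil.

    ``vel[t] = P(t+1) - P(t-1)`` and ``acc[t] = P(t+2) + P(t-2) - 2 P(t)``
    for interior frames ``t`` in [2, F-3]; the two frames at each boundary
    are filled by copying the nearest interior value (callers that prefer
    to drop them slice with ``[EDGE:-EDGE]``).
    """
    arr = np.asarray(coords, dtype=float)
    F = arr.shape[0]
    if F < 5:
        raise ValueError(f"need at least 5 frames, got {F}")
    vel = np.empty_like(arr)
    acc = np.empty_like(arr)
    vel[2:-2] = arr[3:-1] - arr[1:-3]
    acc[2:-2] = arr[4:] + arr[:-4] - 2.0 * arr[2:-2]
    for e in (0, 1):
        vel[e] = vel[2]
        acc[e] = acc[2]
        vel[F - 1 - e] = vel[F - 3]
        acc[F - 1 - e] = acc[F - 3]
    return vel, acc


def angular_kinematics(
    vel: np.ndarray, acc: np.ndarray, bone_lengths: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Normalise linear differences by per-joint bone lengths d_i."""
    d = np.asarray(bone_lengths, dtype=float)
    if np.any(d <= 0):
        raise ValueError("all bone lengths must be positive")
    return vel / d[None, :, None], acc / d[None, :, None]


def estimate_bone_lengths(
    seq: SkeletonSequence, hip_partner: str | None = None
) -> tuple[np.ndarray, float]:
    """Estimate d_i and the hip-segment length L from the sequence itself.

    d_i is the median over frames of the distance from joint i to its
    parent (the root gets its topology placeholder).  L is the median
    distance from the hip centre to ``hip_partner`` (default: the first
    child of the hip centre in topology order).  Measuring the subject's
    own skeleton is what makes descriptors comparable across body sizes.
    """
    topo = seq.topology
    n = topo.n_joints
    d = np.empty(n)
    for i in range(n):
        p = topo.parent_index[i]
        if p == i or p < 0:
            d[i] = topo.bone_lengths[i]
            continue
        dist = np.linalg.norm(seq.coords[:, i, :] - seq.coords[:, p, :], axis=1)
        d[i] = float(np.median(dist))
    hip = topo.hip_center_index
    if hip_partner is None:
        children = [i for i in range(n) if topo.parent_index[i] == hip and i != hip]
        if not children:
            raise ValueError("hip centre has no child joint to define the hip segment")
        partner = children[0]
    else:
        partner = topo.index_of(hip_partner)
    L = float(np.median(np.linalg.norm(seq.coords[:, partner, :] - seq.coords[:, hip, :], axis=1)))
    if L <= 0:
        raise ValueError("estimated hip segment length is not positive")
    return d, L


def build_descriptor(
    seq: SkeletonSequence,
    config: DescriptorConfig | None = None,
    bone_lengths: np.ndarray | None = None,
    hip_segment_length: float | None = None,
    presmoothed: bool = True,
) -> DescriptorSet:
    """Compute the full descriptor X_t for every usable frame of ``seq``.

    The pose block is hip-centred and normalised by eta/L; the omega/alpha
    blocks are bone-length-normalised differences of the (smoothed)
    absolute coordinates.  ``bone_lengths`` / ``hip_segment_length``
    override the per-sequence estimates (use train-side estimates when a
    protocol requires it).  With ``presmoothed=False`` the configured
    Gaussian filter is applied first.
    """
    config = config or DescriptorConfig()
    if not presmoothed:
        seq = gaussian_smooth(seq, config.smooth_width, config.smooth_sigma)
    if seq.n_frames < 5:
        raise ValueError(f"need at least 5 frames, got {seq.n_frames}")
    topo = seq.topology
    if bone_lengths is None or hip_segment_length is None:
        d_full, L_est = estimate_bone_lengths(seq)
        if bone_lengths is None:
            bone_lengths = d_full
        if hip_segment_length is None:
            hip_segment_length = L_est
    idx = np.array([topo.index_of(nm) for nm in config.selected_joints])
    hip = topo.hip_center_index
    if hip in idx:
        raise ValueError("the hip-centre joint is identically zero after centring; "
                         "remove it from selected_joints")
    d_sel = np.asarray(bone_lengths)[idx]
    rel = (config.eta / hip_segment_length) * (
        seq.coords[:, idx, :] - seq.coords[:, hip:hip + 1, :]
    )
    vel, acc = finite_differences(seq.coords[:, idx, :])
    omega, alpha = angular_kinematics(vel, acc, d_sel)

    F = seq.n_frames
    m = len(idx)
    X = np.concatenate(
        [
            rel.reshape(F, 3 * m),
            config.lam * omega.reshape(F, 3 * m),
            config.eps * alpha.reshape(F, 3 * m),
        ],
        axis=1,
    )
    frame_indices = np.arange(F)
    edge_copied = np.zeros(F, bool)
    edge_copied[:EDGE] = True
    edge_copied[-EDGE:] = True
    if config.edge_policy == "drop":
        keep = slice(EDGE, F - EDGE)
        X = X[keep]
        frame_indices = frame_indices[keep]
        edge_copied = edge_copied[keep]
    return DescriptorSet(
        vectors=X,
        time_labels=frame_indices.copy(),
        frame_indices=frame_indices,
        config=config,
        action_label=seq.action_label,
        source_id=seq.sequence_id,
        edge_copied=edge_copied,
    )
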