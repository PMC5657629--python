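"""Skeleton sequence containers and file I/O.

Two on-disk dialects are supported:

* a canonical long-format CSV (``sequence_id,frame,joint,x,y,z,confidence``)
  with 0-based contiguous frame indices, which round-trips losslessly;
* the plain-text skeleton dialect used by MSR-Action3D-style corpora:
  whitespace-separated numeric rows, a fixed number of rows per frame
  (by default 40 = 20 joints x {world, screen} rows), with an optional
  4th column holding the sensor's per-joint confidence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SkeletonTopology",
    "SkeletonSequence",
    "SkeletonParseError",
    "SkeletonValidationError",
    "read_canonical",
    "write_canonical",
    "read_msr_skeleton",
    "validate_sequence",
    "load_topology",
    "save_topology",
]

CANONICAL_COLUMNS = ("sequence_id", "frame", "joint", "x", "y", "z", "confidence")


class SkeletonParseError(ValueError):
    """Raised when a skeleton file cannot be parsed."""


class SkeletonValidationError(ValueError):
    """Raised when a sequence violates its structural contract."""


@dataclass
class SkeletonTopology:
    """A kinematic tree over named joints.

    ``parent_index[i]`` is the index of the joint that joint ``i`` hangs
    from; the root (the hip centre) is its own parent.  ``bone_lengths[i]``
    is the length d_i of the bone connecting joint ``i`` to its parent,
    in the same (unitless) units as the coordinates; the root entry is a
    placeholder and is never used as a normaliser.  ``hip_segment_length``
    is the length L of the hip segment used to normalise the pose block.

    A topology produced by :meth:`subset` may contain ``parent_index``
    entries of ``-1`` (parent outside the subset); such topologies keep
    their per-joint bone lengths but are no longer trees.
    """

    joint_names: tuple[str, ...]
    parent_index: tuple[int, ...]
    hip_center_index: int
    bone_lengths: np.ndarray
    hip_segment_length: float

    def __post_init__(self) -> None:
        self.joint_names = tuple(self.joint_names)
        self.parent_index = tuple(int(p) for p in self.parent_index)
        self.bone_lengths = np.asarray(self.bone_lengths, dtype=float)
        if len(self.joint_names) != len(self.parent_index):
            raise SkeletonValidationError("joint_names and parent_index lengths differ")
        if self.bone_lengths.shape != (len(self.joint_names),):
            raise SkeletonValidationError("bone_lengths must have one entry per joint")

    @property
    def n_joints(self) -> int:
        return len(self.joint_names)

    def index_of(self, name: str) -> int:
        try:
            return self.joint_names.index(name)
        except ValueError:
            raise KeyError(f"unknown joint name: {name!r}") from None

    def validate(self) -> list[str]:
        """Return a list of violated invariants (empty if valid)."""
        problems: list[str] = []
        n = self.n_joints
        if not (0 <= self.hip_center_index < n):
            problems.append("hip_center_index out of range")
            return problems
        if self.parent_index[self.hip_center_index] != self.hip_center_index:
            problems.append("root joint must be its own parent")
        # every joint must reach the root without cycles
        for i in range(n):
            seen = set()
            j = i
            while j != self.hip_center_index:
                if j in seen or not (0 <= j < n):
                    problems.append(f"joint {self.joint_names[i]} does not reach the root")
                    break
                seen.add(j)
                j = self.parent_index[j]
        nonroot = [i for i in range(n) if i != self.hip_center_index]
        if np.any(self.bone_lengths[nonroot] <= 0):
            problems.append("all bone lengths d_i must be positive")
        if self.hip_segment_length <= 0:
            problems.append("hip_segment_length must be positive")
        return problems

    def subset(self, names: Sequence[str]) -> "SkeletonTopology":
        """Restrict to ``names`` (ordered), keeping the original d_i values.

        Parents that fall outside the subset are marked ``-1``; if the hip
        centre is excluded ``hip_center_index`` is ``-1``.
        """
        idx = [self.index_of(nm) for nm in names]
        pos = {j: k for k, j in enumerate(idx)}
        parents = tuple(pos.get(self.parent_index[j], -1) for j in idx)
        hip = pos.get(self.hip_center_index, -1)
        return SkeletonTopology(
            joint_names=tuple(names),
            parent_index=parents,
            hip_center_index=hip,
            bone_lengths=self.bone_lengths[idx].copy(),
            hip_segment_length=self.hip_segment_length,
        )


@dataclass
class SkeletonSequence:
    """A 3D joint time series: ``coords`` has shape (frames, n_joints, 3)."""

    coords: np.ndarray
    topology: SkeletonTopology
    confidence: np.ndarray | None = None
    frame_rate: float = 30.0
    subject_id: str | None = None
    action_label: str | None = None
    sequence_id: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise SkeletonValidationError(
                f"coords must be (frames, joints, 3), got {self.coords.shape}"
            )
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != self.coords.shape[:2]:
                raise SkeletonValidationError("confidence must be (frames, joints)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_joints(self) -> int:
        return self.coords.shape[1]

    def copy_with(self, **changes) -> "SkeletonSequence":
        out = dataclasses.replace(self, **changes)
        out.metadata = dict(self.metadata, **changes.get("metadata", {}))
        return out


def validate_sequence(seq: SkeletonSequence, topology: SkeletonTopology | None = None) -> list[str]:
    """Check a sequence against its structural invariants.

    Returns a list of human-readable violations, empty when the sequence is
    fit for descriptor computation: joint count matches the topology, no
    non-finite coordinates, and at least 5 frames so the sliding window fits.
    """
    topo = topology or seq.topology
    problems: list[str] = []
    if seq.n_joints != topo.n_joints:
        problems.append(
            f"sequence has {seq.n_joints} joints but topology defines {topo.n_joints}"
        )
    if seq.n_frames < 5:
        problems.append(f"frames < 5 (got {seq.n_frames}); the 5-frame window cannot fit")
    bad = ~np.isfinite(seq.coords)
    if bad.any():
        frames, joints, _ = np.nonzero(bad)
        for f, j in sorted(set(zip(frames.tolist(), joints.tolist()))):
            problems.append(f"non-finite coordinate at frame {f}, joint {j} ({topo.joint_names[j]})")
    if seq.confidence is not None:
        if ((seq.confidence < 0) | (seq.confidence > 1)).any():
            problems.append("confidence values outside [0, 1]")
    return problems


# ---------------------------------------------------------------------------
# canonical CSV dialect
# ---------------------------------------------------------------------------

def write_canonical(seq: SkeletonSequence, path: str | Path) -> None:
    """Write a sequence as canonical long-format CSV.

    Rows are frame-major then in topology joint order, with full float
    precision, so two writes of the same sequence are byte-identical and a
    write/read round trip preserves coordinates bitwise.  A missing
    confidence channel is written as 1.0.
    """
    path = Path(path)
    F, n = seq.n_frames, seq.n_joints
    conf = seq.confidence if seq.confidence is not None else np.ones((F, n))
    sid = seq.sequence_id if seq.sequence_id is not None else "seq"
    frames = np.repeat(np.arange(F), n)
    joints = np.tile(np.asarray(seq.topology.joint_names, dtype=object), F)
    flat = seq.coords.reshape(F * n, 3)
    df = pd.DataFrame(
        {
            "sequence_id": sid,
            "frame": frames,
            "joint": joints,
            "x": flat[:, 0],
            "y": flat[:, 1],
            "z": flat[:, 2],
            "confidence": conf.reshape(F * n),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def read_canonical(path: str | Path, topology: SkeletonTopology) -> SkeletonSequence:
    """Read a canonical CSV written by :func:`write_canonical`.

    Frames must be numbered contiguously from 0 and every (frame, joint)
    cell must be present; gaps and unknown joint names are reported with
    their location.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = set(CANONICAL_COLUMNS) - set(df.columns)
    if missing_cols:
        raise SkeletonParseError(f"{path}: missing columns {sorted(missing_cols)}")
    names = topology.joint_names
    unknown = set(df["joint"].unique()) - set(names)
    if unknown:
        raise SkeletonParseError(f"{path}: unknown joint names {sorted(unknown)}")
    if len(df) == 0:
        raise SkeletonParseError(f"{path}: no data rows")
    frames = np.sort(df["frame"].unique())
    F = len(frames)
    if frames[0] != 0 or not np.array_equal(frames, np.arange(F)):
        raise SkeletonParseError(
            f"{path}: frame indices must be contiguous and 0-based "
            f"(found range {frames[0]}..{frames[-1]} over {F} distinct frames)"
        )
    n = topology.n_joints
    coords = np.full((F, n, 3), np.nan)
    conf = np.ones((F, n))
    jidx = df["joint"].map({nm: i for i, nm in enumerate(names)}).to_numpy()
    fidx = df["frame"].to_numpy()
    coords[fidx, jidx, 0] = df["x"].to_numpy()
    coords[fidx, jidx, 1] = df["y"].to_numpy()
    coords[fidx, jidx, 2] = df["z"].to_numpy()
    conf[fidx, jidx] = df["confidence"].to_numpy()
    gaps = np.argwhere(np.isnan(coords[:, :, 0]))
    if len(gaps):
        f, j = gaps[0]
        raise SkeletonParseError(
            f"{path}: missing joint {names[j]!r} in frame {f} "
            f"({len(gaps)} missing (frame, joint) cells in total)"
        )
    sids = df["sequence_id"].unique()
    return SkeletonSequence(
        coords=coords,
        topology=topology,
        confidence=conf,
        sequence_id=str(sids[0]) if len(sids) == 1 else None,
    )


# ---------------------------------------------------------------------------
# MSR-Action3D-style plain-text dialect
# ---------------------------------------------------------------------------

def read_msr_skeleton(
    path: str | Path,
    topology: SkeletonTopology,
    rows_per_frame: int = 40,
    keep_block: str = "world",
    layout: str = "interleaved",
) -> SkeletonSequence:
    """Read an MSR-Action3D-style whitespace-separated skeleton file.

    Each frame occupies ``rows_per_frame`` consecutive rows.  With the
    default 40 rows per frame, each joint contributes a pair of rows
    ({world, screen} coordinates); ``layout`` says how the two blocks are
    arranged ("interleaved": world/screen rows alternate per joint;
    "stacked": all world rows then all screen rows) and ``keep_block``
    selects which one ("world" or "screen") is kept.  With 20 rows per
    frame every row is a joint and both options are ignored.  A 4th
    numeric column, when present, is stored as per-joint confidence.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                rows.append([float(tok) for tok in tokens])
            except ValueError:
                raise SkeletonParseError(
                    f"{path}: non-numeric token on line {lineno}: {line.strip()!r}"
                ) from None
    if not rows:
        raise SkeletonParseError(f"{path}: empty file")
    n = topology.n_joints
    if rows_per_frame % n != 0:
        raise SkeletonParseError(
            f"rows_per_frame={rows_per_frame} is not a multiple of n_joints={n}"
        )
    if len(rows) % rows_per_frame != 0:
        first_bad = (len(rows) // rows_per_frame) * rows_per_frame + 1
        raise SkeletonParseError(
            f"{path}: row count {len(rows)} is not a multiple of "
            f"rows_per_frame={rows_per_frame}; incomplete frame starts at row {first_bad}"
        )
    ncols = {len(r) for r in rows}
    if len(ncols) != 1:
        raise SkeletonParseError(f"{path}: inconsistent column counts {sorted(ncols)}")
    width = ncols.pop()
    if width < 3:
        raise SkeletonParseError(f"{path}: rows must have at least x y z columns (got {width})")
    arr = np.asarray(rows, dtype=float)
    F = len(rows) // rows_per_frame
    arr = arr.reshape(F, rows_per_frame, width)
    blocks = rows_per_frame // n
    if blocks > 1:
        which = {"world": 0, "screen": 1}.get(keep_block)
        if which is None or which >= blocks:
            raise SkeletonParseError(f"keep_block={keep_block!r} not available")
        if layout == "interleaved":
            arr = arr[:, which::blocks, :]
        elif layout == "stacked":
            arr = arr[:, which * n:(which + 1) * n, :]
        else:
            raise SkeletonParseError(f"unknown layout {layout!r}")
    coords = arr[:, :, :3]
    conf = np.clip(arr[:, :, 3], 0.0, 1.0) if width >= 4 else None
    return SkeletonSequence(
        coords=coords,
        topology=topology,
        confidence=conf,
        sequence_id=path.stem,
        metadata={
            "dialect": "msr",
            "rows_per_frame": rows_per_frame,
            "layout": layout if blocks > 1 else "single",
            "keep_block": keep_block if blocks > 1 else "all",
        },
    )


def repair_gaps(seq: SkeletonSequence, max_gap: int = 2) -> SkeletonSequence:
    """Linearly interpolate NaN joints over gaps of at most ``max_gap`` frames.

    Sequences with longer gaps (or NaN at the boundaries) still fail
    validation afterwards; this is an opt-in repair, off by default in all
    pipelines.
    """
    coords = seq.coords.copy()
    F = seq.n_frames
    t = np.arange(F)
    for j in range(seq.n_joints):
        for d in range(3):
            col = coords[:, j, d]
            bad = np.isnan(col)
            if not bad.any() or bad.all():
                continue
            # run-length check on gaps
            runs = []
            start = None
            for f in range(F):
                if bad[f] and start is None:
                    start = f
                elif not bad[f] and start is not None:
                    runs.append((start, f - 1))
                    start = None
            if start is not None:
                runs.append((start, F - 1))
            ok = all(b - a + 1 <= max_gap and a > 0 and b < F - 1 for a, b in runs)
            if ok:
                col[bad] = np.interp(t[bad], t[~bad], col[~bad])
    return seq.copy_with(coords=coords)


# ---------------------------------------------------------------------------
# topology definition files
# ---------------------------------------------------------------------------

def save_topology(topology: SkeletonTopology, path: str | Path) -> None:
    doc = {
        "joints": [
            {
                "name": nm,
                "parent": topology.joint_names[topology.parent_index[i]]
                if topology.parent_index[i] >= 0
                else None,
                "bone_length": float(topology.bone_lengths[i]),
            }
            for i, nm in enumerate(topology.joint_names)
        ],
        "hip_center": topology.joint_names[topology.hip_center_index],
        "hip_segment_length": float(topology.hip_segment_length),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_topology(path: str | Path) -> SkeletonTopology:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    names = [j["name"] for j in doc["joints"]]
    pos = {nm: i for i, nm in enumerate(names)}
    parents = []
    for j in doc["joints"]:
        p = j.get("parent")
        parents.append(pos[p] if p is not None else pos[j["name"]])
    topo = SkeletonTopology(
        joint_names=tuple(names),
        parent_index=tuple(parents),
        hip_center_index=pos[doc["hip_center"]],
        bone_lengths=np.array([float(j["bone_length"]) for j in doc["joints"]]),
        hip_segment_length=float(doc["hip_segment_length"]),
    )
    problems = topo.validate()
    if problems:
        raise SkeletonValidationError(f"{path}: " + "; ".join(problems))
    return topo
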