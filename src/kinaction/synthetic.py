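"""Synthetic skeleton-motion generator.

Generates labelled 20-joint skeleton sequences with the statistical
structure the recognition method assumes: actions are class-specific
*angular* programs on a kinematic chain (so the same action performed by
a small and a large subject traces the same angles), subjects differ in
global scale, per-bone length jitter and speed, sensors add isotropic
Gaussian jitter, and sequences open with a frozen idle posture before the
action starts.  Concatenating sequences yields unsegmented streams with
known per-frame ground truth.

Joint direction vectors are parameterised by spherical angles
(polar theta from the +y axis, azimuth phi in the x-z plane); each
animated joint follows ``angle(t) = rest + amplitude * sin(2 pi f tau +
phase)`` with integer frequency f over the action, so trajectories are
smooth, band-limited, and return to the rest pose at the end of each
repetition.  A ``direction = -1`` template plays the same program
time-reversed: an identical spatial path with opposite velocities, the
classic pull-vs-push confusion that position-only descriptors cannot
resolve.  Everything is a pure function of its parameters and seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .skeleton_io import SkeletonSequence, SkeletonTopology

__all__ = [
    "JointProgram",
    "ActionTemplate",
    "SubjectProfile",
    "GroundTruth",
    "StreamTruth",
    "SyntheticDataset",
    "make_topology",
    "make_subject",
    "default_templates",
    "generate_action_sequence",
    "generate_dataset",
    "make_stream",
    "derive_seed",
]

MASK64 = (1 << 64) - 1

# (name, parent, bone length, rest theta, rest phi)
_DEFAULT_SKELETON = [
    ("hip_center",      "hip_center",      0.25, 0.0,         0.0),
    ("spine",           "hip_center",      0.25, 0.0,         0.0),
    ("shoulder_center", "spine",           0.25, 0.0,         0.0),
    ("head",            "shoulder_center", 0.18, 0.0,         0.0),
    ("shoulder_left",   "shoulder_center", 0.18, np.pi / 2,   np.pi),
    ("elbow_left",      "shoulder_left",   0.28, 2.70,        np.pi),
    ("wrist_left",      "elbow_left",      0.25, 2.85,        np.pi),
    ("hand_left",       "wrist_left",      0.08, 2.95,        np.pi),
    ("shoulder_right",  "shoulder_center", 0.18, np.pi / 2,   0.0),
    ("elbow_right",     "shoulder_right",  0.28, 2.70,        0.0),
    ("wrist_right",     "elbow_right",     0.25, 2.85,        0.0),
    ("hand_right",      "wrist_right",     0.08, 2.95,        0.0),
    ("hip_left",        "hip_center",      0.12, np.pi / 2,   np.pi),
    ("knee_left",       "hip_left",        0.40, 3.05,        np.pi),
    ("ankle_left",      "knee_left",       0.38, 3.10,        np.pi),
    ("foot_left",       "ankle_left",      0.15, np.pi / 2,   np.pi / 2),
    ("hip_right",       "hip_center",      0.12, np.pi / 2,   0.0),
    ("knee_right",      "hip_right",       0.40, 3.05,        0.0),
    ("ankle_right",     "knee_right",      0.38, 3.10,        0.0),
    ("foot_right",      "ankle_right",     0.15, np.pi / 2,   np.pi / 2),
]


def derive_seed(master: int, *parts) -> int:
    """Stable splitmix64-style mix of a master seed and identifiers.

    Independent of generation order, so a dataset is reproducible even if
    its sequences are generated in a different order.
    """
    def mix(x: int) -> int:
        x = (x + 0x9E3779B97F4A7C15) & MASK64
        z = x
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & MASK64
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & MASK64
        return (z ^ (z >> 31)) & MASK64

    h = mix(int(master) & MASK64)
    for p in parts:
        if isinstance(p, int):
            token = p & MASK64
        else:
            token = int.from_bytes(
                hashlib.blake2b(str(p).encode(), digest_size=8).digest(), "big"
            )
        h = mix(h ^ token)
    return h & ((1 << 63) - 1)


def make_topology(
    n_joints: int = 20, base_bone_lengths: dict[str, float] | None = None
) -> SkeletonTopology:
    """The default 20-joint Kinect-v1-style kinematic tree.

    Hip-centre root, a spine/shoulder-centre/head chain, two 4-joint arms
    and two 3-joint legs.  ``base_bone_lengths`` overrides individual bone
    lengths by joint name; the hip segment is the hip-centre -> spine bone.
    """
    if n_joints != 20:
        raise ValueError("the default topology has exactly 20 joints")
    over = base_bone_lengths or {}
    names, parents, lengths = [], [], []
    for name, parent, length, _, _ in _DEFAULT_SKELETON:
        names.append(name)
        parents.append(parent)
        lengths.append(float(over.get(name, length)))
    if any(l <= 0 for l in lengths):
        raise ValueError("bone lengths must be positive")
    pos = {nm: i for i, nm in enumerate(names)}
    topo = SkeletonTopology(
        joint_names=tuple(names),
        parent_index=tuple(pos[p] for p in parents),
        hip_center_index=pos["hip_center"],
        bone_lengths=np.array(lengths),
        hip_segment_length=float(lengths[pos["spine"]]),
    )
    problems = topo.validate()
    if problems:
        raise ValueError("; ".join(problems))
    return topo


_REST_ANGLES = {name: (theta, phi) for name, _, _, theta, phi in _DEFAULT_SKELETON}


@dataclass(frozen=True)
class JointProgram:
    """Sinusoidal angle program for one joint: amplitude (rad) per
    spherical angle, integer cycles per action, and phases."""

    amp_theta: float
    amp_phi: float
    freq: int = 2
    phase_theta: float = 0.0
    phase_phi: float = np.pi / 3


# every class starts from the same modest whole-body "wind-up" motion for
# the first few action frames — the shared starting style that makes early
# frames ambiguous across classes and earns them low training confidence
WINDUP_PROGRAMS: dict[str, JointProgram] = {
    **{f"{j}_{s}": JointProgram(0.35, 0.28, 1)
       for j in ("elbow", "wrist", "hand") for s in ("left", "right")},
    **{f"{j}_{s}": JointProgram(0.25, 0.2, 1)
       for j in ("knee", "ankle", "foot") for s in ("left", "right")},
    "head": JointProgram(0.15, 0.12, 1),
}
WINDUP_ROOT_AMP = (0.36, 0.40, 0.45)


@dataclass(frozen=True)
class ActionTemplate:
    """A class-defining motion program on the kinematic chain."""

    class_id: str
    joint_programs: dict[str, JointProgram]
    duration: int = 45                       # frames at speed 1
    direction: int = 1                       # -1 plays the path time-reversed
    root_amp: tuple[float, float, float] = (0.0, 0.0, 0.0)
    root_freq: int = 2
    root_phases: tuple[float, float, float] = (0.0, np.pi, 0.35)
    windup_frames: int = 10                  # shared starting-style span, at speed 1

    def __post_init__(self) -> None:
        if self.duration < 5:
            raise ValueError("duration must be >= 5 frames")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        moving = any(
            p.amp_theta != 0 or p.amp_phi != 0 for p in self.joint_programs.values()
        ) or any(a != 0 for a in self.root_amp)
        if not moving:
            raise ValueError("template must animate at least one joint")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject anthropometry and execution style."""

    subject_id: str
    scale: float = 1.0                  # global bone-length scale
    bone_jitter: tuple[float, ...] = () # per-joint multiplicative jitter
    speed: float = 1.0                  # >1 performs the action faster
    noise_sd: float = 0.002             # coordinate jitter, coordinate units

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not (0.5 <= self.speed <= 2.0):
            raise ValueError("speed factor out of plausible range")


def make_subject(
    subject_id: str,
    seed: int,
    scale_range: tuple[float, float] = (0.85, 1.15),
    bone_jitter_frac: float = 0.05,
    speed_range: tuple[float, float] = (0.9, 1.1),
    noise_sd: float = 0.002,
    n_joints: int = 20,
) -> SubjectProfile:
    """Draw a subject's scale, per-bone jitter and speed from its seed."""
    rng = np.random.default_rng(seed)
    return SubjectProfile(
        subject_id=subject_id,
        scale=float(rng.uniform(*scale_range)),
        bone_jitter=tuple(rng.uniform(1 - bone_jitter_frac, 1 + bone_jitter_frac, n_joints)),
        speed=float(rng.uniform(*speed_range)),
        noise_sd=noise_sd,
    )


@dataclass
class GroundTruth:
    """What the generator knows about one sequence."""

    class_id: str
    onset: int                      # first action frame (0-based)
    labels: np.ndarray              # per-frame regularized label; -1 = idle prefix
    n_action_frames: int            # frames per single performance
    t_as: int = 0                   # end of the shared starting style, frames after onset
    rep_spans: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class StreamTruth:
    """Per-frame ground truth of a concatenated stream.

    ``frame_class`` holds the owning sequence's class per frame, with
    ``None`` on idle-prefix frames (no action is being performed there).
    """

    frame_class: np.ndarray             # object array: class or None per frame
    segments: list[tuple[int, int, str]]  # (start, end_exclusive, class)


def _forward_kinematics(
    topology: SkeletonTopology,
    bone_lengths: np.ndarray,
    theta: np.ndarray,
    phi: np.ndarray,
    root_offset: np.ndarray,
) -> np.ndarray:
    """Positions from per-frame joint angles.  ``theta``/``phi`` are
    (frames, n_joints); returns (frames, n_joints, 3)."""
    F, n = theta.shape
    dirs = np.empty((F, n, 3))
    st = np.sin(theta)
    dirs[:, :, 0] = st * np.cos(phi)
    dirs[:, :, 1] = np.cos(theta)
    dirs[:, :, 2] = st * np.sin(phi)
    pos = np.zeros((F, n, 3))
    order = _topo_order(topology)
    root = topology.hip_center_index
    pos[:, root, :] = root_offset
    for j in order:
        if j == root:
            continue
        p = topology.parent_index[j]
        pos[:, j, :] = pos[:, p, :] + bone_lengths[j] * dirs[:, j, :]
    return pos


def _topo_order(topology: SkeletonTopology) -> list[int]:
    order: list[int] = []
    seen: set[int] = set()

    def visit(j: int) -> None:
        p = topology.parent_index[j]
        if p != j and p not in seen:
            visit(p)
        if j not in seen:
            seen.add(j)
            order.append(j)

    for j in range(topology.n_joints):
        visit(j)
    return order


def generate_action_sequence(
    template: ActionTemplate,
    profile: SubjectProfile,
    topology: SkeletonTopology | None = None,
    idle_prefix: int = 30,
    idle_suffix: int = 0,
    repetitions: int = 1,
    rep_gap: int = 10,
    seed: int = 0,
    amp_jitter: float = 0.08,
    phase_jitter: float = 0.08,
) -> tuple[SkeletonSequence, GroundTruth]:
    """Synthesize one labelled sequence.

    Layout: ``idle_prefix`` frames frozen at the first action pose, then
    ``repetitions`` performances separated by ``rep_gap`` frozen frames,
    then ``idle_suffix`` frozen frames — all with additive Gaussian
    coordinate jitter.  Regularized labels count frames from the onset
    (so second performances simply carry larger labels, as the training
    re-basing produces).  The same (template, profile, seed) always
    yields a bitwise-identical sequence.
    """
    topology = topology or make_topology()
    rng = np.random.default_rng(seed)
    n = topology.n_joints
    n_action = max(5, int(round(template.duration / profile.speed)))

    # per-frame phase of the program, in [0, 1)
    u = np.arange(n_action)
    if template.direction < 0:
        u = u[::-1]
    tau = u * profile.speed / template.duration

    # per-sequence execution style: no two performances, even by the same
    # subject, trace exactly the same amplitudes and phases
    amp_f = rng.normal(1.0, amp_jitter, n).clip(0.7, 1.3)
    dphase = rng.normal(0.0, phase_jitter, n)

    def _angles(programs: dict[str, JointProgram], phase_tau: np.ndarray):
        th = np.empty((len(phase_tau), n))
        ph = np.empty((len(phase_tau), n))
        for j, name in enumerate(topology.joint_names):
            th0, ph0 = _REST_ANGLES.get(name, (0.0, 0.0))
            prog = programs.get(name)
            if prog is None:
                th[:, j] = th0
                ph[:, j] = ph0
            else:
                arg = 2 * np.pi * prog.freq * phase_tau + dphase[j]
                a = amp_f[j]
                th[:, j] = th0 + a * prog.amp_theta * np.sin(arg + prog.phase_theta)
                ph[:, j] = ph0 + a * prog.amp_phi * np.sin(arg + prog.phase_phi)
        return th, ph

    def _root(amp3, freq: int, phase_tau: np.ndarray):
        amp = np.asarray(amp3)
        phases = np.asarray(template.root_phases)
        arg1 = 2 * np.pi * freq * phase_tau[:, None] + phases[None, :]
        arg2 = 2 * np.pi * (freq + 1) * phase_tau[:, None] + phases[None, :]
        # two harmonics per dimension so the whole-body sway velocity never
        # vanishes in any dimension for more than an instant
        return amp[None, :] * (np.sin(arg1) + 0.55 * np.sin(arg2))

    theta, phi = _angles(template.joint_programs, tau)
    root = _root(template.root_amp, template.root_freq, tau)

    # shared starting style: blend from the common wind-up program into the
    # class program over the first windup frames of the performance
    n_windup = int(round(template.windup_frames / profile.speed))
    n_windup = min(n_windup, n_action)
    if n_windup > 0:
        tau_perf = np.arange(n_action) * profile.speed / template.duration
        th_w, ph_w = _angles(WINDUP_PROGRAMS, tau_perf[:n_windup])
        root_w = _root(WINDUP_ROOT_AMP, 1, tau_perf[:n_windup])
        # first half of the wind-up is purely shared, then a smoothstep
        # hand-over into the class program
        u_w = np.arange(n_windup)
        x = np.clip((u_w - n_windup / 2) / max(n_windup - n_windup / 2, 1), 0.0, 1.0)
        beta = (3 * x ** 2 - 2 * x ** 3)[:, None]
        theta[:n_windup] = (1 - beta) * th_w + beta * theta[:n_windup]
        phi[:n_windup] = (1 - beta) * ph_w + beta * phi[:n_windup]
        root[:n_windup] = (1 - beta) * root_w + beta * root[:n_windup]
    root = root * profile.scale

    jitter = np.asarray(profile.bone_jitter) if profile.bone_jitter else np.ones(n)
    bones = topology.bone_lengths * profile.scale * jitter
    action = _forward_kinematics(topology, bones, theta, phi, root)

    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    rep_spans: list[tuple[int, int]] = []
    cursor = 0
    if idle_prefix:
        blocks.append(np.repeat(action[:1], idle_prefix, axis=0))
        labels.append(np.full(idle_prefix, -1))
        cursor += idle_prefix
    onset = cursor
    for r in range(repetitions):
        if r > 0 and rep_gap:
            blocks.append(np.repeat(action[-1:], rep_gap, axis=0))
            labels.append(np.arange(cursor, cursor + rep_gap) - onset)
            cursor += rep_gap
        blocks.append(action)
        rep_spans.append((cursor, cursor + n_action))
        labels.append(np.arange(cursor, cursor + n_action) - onset)
        cursor += n_action
    if idle_suffix:
        blocks.append(np.repeat(action[-1:], idle_suffix, axis=0))
        labels.append(np.arange(cursor, cursor + idle_suffix) - onset)
        cursor += idle_suffix

    coords = np.concatenate(blocks, axis=0)
    coords = coords + rng.normal(0.0, profile.noise_sd, coords.shape)
    scaled_topo = SkeletonTopology(
        joint_names=topology.joint_names,
        parent_index=topology.parent_index,
        hip_center_index=topology.hip_center_index,
        bone_lengths=bones,
        hip_segment_length=float(bones[topology.index_of("spine")]),
    )
    seq = SkeletonSequence(
        coords=coords,
        topology=scaled_topo,
        subject_id=profile.subject_id,
        action_label=template.class_id,
        metadata={"seed": seed, "true_onset": onset},
    )
    gt = GroundTruth(
        class_id=template.class_id,
        onset=onset,
        labels=np.concatenate(labels),
        n_action_frames=n_action,
        t_as=n_windup,
        rep_spans=rep_spans,
    )
    return seq, gt


def _arm(side: str, amp_t: float, amp_p: float, freq: int, dphase: float = 0.0):
    return {
        f"elbow_{side}": JointProgram(amp_t, amp_p, freq, dphase, np.pi / 3 + dphase),
        f"wrist_{side}": JointProgram(amp_t * 1.15, amp_p * 1.1, freq, dphase + 0.2,
                                      np.pi / 3 + dphase + 0.2),
        f"hand_{side}": JointProgram(amp_t * 1.25, amp_p * 1.2, freq, dphase + 0.35,
                                     np.pi / 3 + dphase + 0.35),
    }


def _leg(side: str, amp_t: float, amp_p: float, freq: int, dphase: float = 0.0):
    return {
        f"knee_{side}": JointProgram(amp_t, amp_p, freq, dphase, np.pi / 3 + dphase),
        f"ankle_{side}": JointProgram(amp_t * 1.1, amp_p * 1.05, freq, dphase + 0.2,
                                      np.pi / 3 + dphase + 0.2),
        f"foot_{side}": JointProgram(amp_t * 1.2, amp_p * 1.1, freq, dphase + 0.3,
                                     np.pi / 3 + dphase + 0.3),
    }


def default_templates(duration: int = 45) -> list[ActionTemplate]:
    """Five calisthenic action classes, including a direction-reversed
    pair ('punch_forward' / 'punch_recoil') that shares a spatial path and
    differs only in traversal direction."""
    punch_programs = {
        **_arm("right", 1.2, 1.1, 2),
        **_arm("left", 0.3, 0.2, 2, 0.5),
        **_leg("left", 0.22, 0.15, 2, 0.3),
        **_leg("right", 0.22, 0.15, 2, 0.8),
        "head": JointProgram(0.18, 0.15, 2),
    }
    return [
        ActionTemplate(
            class_id="jumping_jack",
            joint_programs={
                **_arm("left", 1.2, 0.7, 2),
                **_arm("right", 1.2, 0.7, 2, np.pi),
                **_leg("left", 0.5, 0.35, 2),
                **_leg("right", 0.5, 0.35, 2, np.pi),
                "head": JointProgram(0.22, 0.18, 2),
            },
            duration=duration,
            root_amp=(0.35, 0.50, 0.35),
            root_freq=2,
        ),
        ActionTemplate(
            class_id="punch_forward",
            joint_programs=punch_programs,
            duration=duration,
            direction=1,
            root_amp=(0.46, 0.58, 0.54),
            root_freq=2,
        ),
        ActionTemplate(
            class_id="punch_recoil",
            joint_programs=punch_programs,
            duration=duration,
            direction=-1,
            root_amp=(0.46, 0.58, 0.54),
            root_freq=2,
        ),
        ActionTemplate(
            class_id="kick_left",
            joint_programs={
                **_leg("left", 1.1, 0.7, 2),
                **_leg("right", 0.18, 0.15, 2, 0.6),
                **_arm("left", 0.45, 0.3, 2, 0.4),
                **_arm("right", 0.45, 0.3, 2, 1.1),
                "head": JointProgram(0.15, 0.12, 2),
            },
            duration=duration,
            root_amp=(0.38, 0.50, 0.38),
            root_freq=2,
        ),
        ActionTemplate(
            class_id="arm_wave",
            joint_programs={
                **_arm("left", 1.0, 1.1, 3),
                **_arm("right", 1.0, 1.1, 3, np.pi / 2),
                **_leg("left", 0.15, 0.12, 3, 0.2),
                **_leg("right", 0.15, 0.12, 3, 0.7),
                "head": JointProgram(0.35, 0.28, 3),
            },
            duration=duration,
            root_amp=(0.30, 0.45, 0.30),
            root_freq=3,
        ),
    ]


@dataclass
class SyntheticDataset:
    """A reproducible labelled corpus of synthetic sequences."""

    sequences: list[SkeletonSequence]
    ground_truths: dict[str, GroundTruth]
    subjects: tuple[str, ...]
    classes: tuple[str, ...]
    seed: int

    def split_by_subjects(
        self, train_subjects
    ) -> tuple[list[SkeletonSequence], list[SkeletonSequence]]:
        train_subjects = set(train_subjects)
        unknown = train_subjects - set(self.subjects)
        if unknown:
            raise ValueError(f"unknown subjects {sorted(unknown)}")
        train = [s for s in self.sequences if s.subject_id in train_subjects]
        test = [s for s in self.sequences if s.subject_id not in train_subjects]
        return train, test

    def split_odd_even(self) -> tuple[list[SkeletonSequence], list[SkeletonSequence]]:
        """Odd-numbered subjects train, even-numbered test (cross-subject)."""
        odd = {s for i, s in enumerate(self.subjects, start=1) if i % 2 == 1}
        return self.split_by_subjects(odd)


def generate_dataset(
    templates: list[ActionTemplate] | None = None,
    n_subjects: int = 8,
    reps_per_subject: int = 2,
    seed: int = 0,
    idle_prefix: int = 30,
    repetitions: int = 1,
    noise_sd: float = 0.002,
    topology: SkeletonTopology | None = None,
) -> SyntheticDataset:
    """Class-balanced corpus: every subject performs every action
    ``reps_per_subject`` times.  Per-sequence seeds are mixed from the
    master seed and the (class, subject, rep) identifiers only."""
    templates = templates if templates is not None else default_templates()
    if len(templates) < 2 or n_subjects < 2:
        raise ValueError("need at least 2 templates and 2 subjects")
    topology = topology or make_topology()
    subjects = tuple(f"s{i:02d}" for i in range(1, n_subjects + 1))
    profiles = {
        sid: make_subject(sid, derive_seed(seed, "subject", sid), noise_sd=noise_sd)
        for sid in subjects
    }
    sequences: list[SkeletonSequence] = []
    gts: dict[str, GroundTruth] = {}
    for tpl in templates:
        for sid in subjects:
            for rep in range(reps_per_subject):
                sseed = derive_seed(seed, tpl.class_id, sid, rep)
                seq, gt = generate_action_sequence(
                    tpl, profiles[sid], topology,
                    idle_prefix=idle_prefix, repetitions=repetitions, seed=sseed,
                )
                seq.sequence_id = f"{sid}_{tpl.class_id}_r{rep}"
                sequences.append(seq)
                gts[seq.sequence_id] = gt
    return SyntheticDataset(
        sequences=sequences,
        ground_truths=gts,
        subjects=subjects,
        classes=tuple(t.class_id for t in templates),
        seed=seed,
    )


def make_stream(
    sequences: list[SkeletonSequence],
    ground_truths: dict[str, GroundTruth] | None = None,
    order: list[int] | None = None,
) -> tuple[SkeletonSequence, StreamTruth]:
    """Concatenate sequences (idle prefixes included) into one unsegmented
    stream with per-frame ground truth."""
    if not sequences:
        raise ValueError("need at least one sequence")
    if order is not None:
        sequences = [sequences[i] for i in order]
    coords = np.concatenate([s.coords for s in sequences], axis=0)
    per_seq_class = []
    for s in sequences:
        fc = np.full(s.n_frames, s.action_label, dtype=object)
        if ground_truths is not None and s.sequence_id in ground_truths:
            fc[ground_truths[s.sequence_id].labels < 0] = None
        per_seq_class.append(fc)
    frame_class = np.concatenate(per_seq_class)
    segments = []
    cursor = 0
    for s in sequences:
        segments.append((cursor, cursor + s.n_frames, s.action_label))
        cursor += s.n_frames
    stream = SkeletonSequence(
        coords=coords,
        topology=sequences[0].topology,
        sequence_id="stream",
        metadata={"n_segments": len(sequences)},
    )
    return stream, StreamTruth(frame_class=frame_class, segments=segments)
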