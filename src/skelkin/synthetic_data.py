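"""Synthetic models, motions and corrupted marker observations.

The generator produces (i) a full-body humanoid skeletal model with a
configurable reduced spine, (ii) smooth ground-truth joint-angle trajectories
as banks of sinusoids inside each coordinate's range, and (iii) corrupted
marker observations: i.i.d. Gaussian jitter, a constant per-marker systematic
bias (emulating the 30-50 mm joint-center errors and 12-25 mm placement
variation reported for image-based keypoint detectors), and contiguous
occlusion gaps.  Everything is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kinematics import neutral_angles
from .model_io import (
    BodyDefinition,
    DegreeOfFreedom,
    GROUND,
    JointDefinition,
    MarkerDefinition,
    MarkerTrajectory,
    MotionSequence,
    SkeletalModel,
)
from .scaling_ik import ScalePairConfig

__all__ = [
    "ModelSpec",
    "TrajectorySpec",
    "NoiseSpec",
    "make_default_model",
    "default_scale_config",
    "simulate_motion",
    "corrupt_markers",
]

_X = (1.0, 0.0, 0.0)
_Y = (0.0, 1.0, 0.0)
_Z = (0.0, 0.0, 1.0)
_INF = math.inf


@dataclass
class ModelSpec:
    """Size parameters of the generated humanoid fixture."""

    spine_segments: int = 3  # lumbar-to-cervical chain; 9 matches a per-vertebra-group model


@dataclass
class TrajectorySpec:
    """Smooth ground-truth motion: a sinusoid bank per coordinate.

    Each coordinate moves as ``mean + sum_k a_k sin(2 pi f_k t + phi_k)`` with
    the total amplitude bounded by ``amplitude_fraction`` of the coordinate's
    half-range, so motions always respect joint limits.  The root rotates
    slowly and smoothly.  ``bank`` may pin explicit ``(amplitude, frequency,
    phase)`` triples per coordinate; otherwise they are drawn from ``seed``.
    """

    duration: float = 8.0  # s
    rate: float = 25.0  # Hz
    freq_range: tuple[float, float] = (0.1, 1.0)  # Hz
    amplitude_fraction: float = 0.35
    n_harmonics: int = 2
    root_amplitude: float = 0.25  # rad
    root_freq_range: tuple[float, float] = (0.05, 0.2)  # Hz
    hold_s: float = 0.0  # initial neutral-pose hold (calibration window)
    ramp_s: float = 0.0  # smoothstep blend from neutral into the motion
    bank: dict | None = None
    seed: int = 0

    def validate(self) -> "TrajectorySpec":
        if self.rate <= 2 * self.freq_range[1]:
            raise ValueError("sampling rate must exceed twice the maximum frequency")
        if self.duration <= 0 or self.n_harmonics < 1:
            raise ValueError("duration must be > 0 and n_harmonics >= 1")
        if not 0 <= self.amplitude_fraction <= 1:
            raise ValueError("amplitude_fraction must be in [0, 1]")
        return self


@dataclass
class NoiseSpec:
    """Marker corruption model.

    Defaults mirror reported keypoint-detector error magnitudes: 5 mm
    Gaussian jitter and a constant per-marker bias with norm drawn uniformly
    from 30-50 mm (direction uniform on the sphere).  Occlusion marks
    contiguous windows of frames missing, off by default.
    """

    gaussian_sigma: float = 0.005  # m
    bias_norm_range: tuple[float, float] = (0.03, 0.05)  # m
    occlusion_rate: float = 0.0  # expected fraction of occluded frames
    occlusion_window: int = 10  # frames per gap
    seed: int = 0

    def validate(self) -> "NoiseSpec":
        lo, hi = self.bias_norm_range
        if self.gaussian_sigma < 0 or not 0 <= lo <= hi:
            raise ValueError("sigma must be >= 0 and 0 <= bias lo <= hi")
        if not 0 <= self.occlusion_rate <= 1 or self.occlusion_window < 1:
            raise ValueError("occlusion_rate in [0,1] and occlusion_window >= 1")
        return self


# ---------------------------------------------------------------------------
# Default humanoid model
# ---------------------------------------------------------------------------


def _markers_for_body(
    body: str,
    x_pair: tuple,
    y_pair: tuple,
    z_pair: tuple,
    bony_axis: str = "y",
) -> list[MarkerDefinition]:
    """Six markers forming axis-aligned pairs (used by distance-based scaling)."""
    out = []
    for axis, (a, b) in (("x", x_pair), ("y", y_pair), ("z", z_pair)):
        bony = axis == bony_axis
        out.append(MarkerDefinition(f"{body}_{axis}p", body, np.asarray(a, float), bony))
        out.append(MarkerDefinition(f"{body}_{axis}m", body, np.asarray(b, float), bony))
    return out


def _limb_markers(body: str, length: float, hx: float, hz: float, direction: float = -1.0):
    """Markers for a segment whose origin is its proximal joint, long axis +-y."""
    mid = direction * length / 2.0
    return _markers_for_body(
        body,
        x_pair=((hx, mid, 0.0), (-hx, mid, 0.0)),
        y_pair=((0.0, 0.0, 0.0), (0.0, direction * length, 0.0)),
        z_pair=((0.0, mid, hz), (0.0, mid, -hz)),
    )


def _dof(name: str, axis, lo: float, hi: float) -> DegreeOfFreedom:
    return DegreeOfFreedom(name, np.asarray(axis, float), (lo, hi))


def _joint(name, parent, child, t_parent, dofs, t_child=(0.0, 0.0, 0.0)):
    zero = np.zeros(3)
    return JointDefinition(
        name=name,
        parent_body=parent,
        child_body=child,
        orientation_in_parent=zero,
        translation_in_parent=np.asarray(t_parent, float),
        orientation_in_child=zero,
        translation_in_child=np.asarray(t_child, float),
        dofs=dofs,
    )


def make_default_model(spec: ModelSpec | None = None) -> SkeletalModel:
    """Full-body humanoid: pelvis root, spine chain, head, two arms, two legs.

    Y is up; each non-root body's origin sits at (or near) its proximal
    joint, so segment lengths live in the parent-side joint translations and
    scale with the parent segment's factors.  Every body carries six markers
    in axis-aligned pairs (>= 3 non-collinear points per segment, enough to
    constrain IK); the longitudinal pairs are flagged bony landmarks.
    Deterministic given the size parameters.
    """
    spec = spec or ModelSpec()
    n_sp = int(spec.spine_segments)
    if n_sp < 1:
        raise ValueError("spine_segments must be >= 1")
    sp_len = 0.45 / n_sp

    bodies: list[BodyDefinition] = [BodyDefinition("pelvis", 240.0, long_axis=0)]
    joints: list[JointDefinition] = []
    markers: list[MarkerDefinition] = _markers_for_body(
        "pelvis",
        x_pair=((0.12, 0.0, 0.0), (-0.12, 0.0, 0.0)),
        y_pair=((0.0, 0.08, 0.0), (0.0, -0.08, 0.0)),
        z_pair=((0.0, 0.0, 0.10), (0.0, 0.0, -0.10)),
        bony_axis="x",
    )

    # spine chain and head
    prev = "pelvis"
    t_p = (0.0, 0.08, 0.0)
    for i in range(1, n_sp + 1):
        body = f"spine_{i}"
        bodies.append(BodyDefinition(body, sp_len * 1e3))
        joints.append(
            _joint(
                f"spine_joint_{i}",
                prev,
                body,
                t_p,
                [
                    _dof(f"spine_{i}_flexion", _Z, -0.35, 0.35),
                    _dof(f"spine_{i}_bending", _X, -0.35, 0.35),
                    _dof(f"spine_{i}_rotation", _Y, -0.35, 0.35),
                ],
            )
        )
        markers += _limb_markers(body, sp_len, 0.07, 0.06, direction=+1.0)
        prev, t_p = body, (0.0, sp_len, 0.0)
    top = prev
    bodies.append(BodyDefinition("head", 220.0))
    joints.append(
        _joint(
            "neck",
            top,
            "head",
            (0.0, sp_len, 0.0),
            [
                _dof("neck_flexion", _Z, -0.7, 0.7),
                _dof("neck_bending", _X, -0.5, 0.5),
                _dof("neck_rotation", _Y, -0.8, 0.8),
            ],
        )
    )
    markers += _limb_markers("head", 0.22, 0.08, 0.09, direction=+1.0)

    # arms and legs, left (-x) and right (+x)
    for side, sx in (("l", -1.0), ("r", +1.0)):
        hum, fore, hand = f"humerus_{side}", f"forearm_{side}", f"hand_{side}"
        bodies += [
            BodyDefinition(hum, 300.0),
            BodyDefinition(fore, 250.0),
            BodyDefinition(hand, 180.0),
        ]
        joints.append(
            _joint(
                f"shoulder_{side}",
                top,
                hum,
                (sx * 0.20, sp_len * 0.8, 0.0),
                [
                    _dof(f"shoulder_flexion_{side}", _Z, -1.5, 1.5),
                    _dof(f"shoulder_abduction_{side}", _X, -1.5, 1.5),
                    _dof(f"shoulder_rotation_{side}", _Y, -1.0, 1.0),
                ],
            )
        )
        joints.append(
            _joint(
                f"elbow_{side}",
                hum,
                fore,
                (0.0, -0.30, 0.0),
                [
                    _dof(f"elbow_flexion_{side}", _Z, -2.4, 0.0),
                    _dof(f"pro_sup_{side}", _Y, -1.3, 1.3),
                ],
                t_child=(0.0, 0.02, 0.0),
            )
        )
        joints.append(
            _joint(
                f"wrist_{side}",
                fore,
                hand,
                (0.0, -0.25, 0.0),
                [
                    _dof(f"wrist_flexion_{side}", _Z, -1.0, 1.0),
                    _dof(f"wrist_deviation_{side}", _X, -0.4, 0.4),
                ],
            )
        )
        markers += _limb_markers(hum, 0.30, 0.04, 0.04)
        markers += _limb_markers(fore, 0.25, 0.035, 0.035)
        markers += _limb_markers(hand, 0.18, 0.03, 0.02)

        fem, tib, foot = f"femur_{side}", f"tibia_{side}", f"foot_{side}"
        bodies += [
            BodyDefinition(fem, 400.0),
            BodyDefinition(tib, 430.0),
            BodyDefinition(foot, 250.0, long_axis=2),
        ]
        joints.append(
            _joint(
                f"hip_{side}",
                "pelvis",
                fem,
                (sx * 0.09, -0.05, 0.0),
                [
                    _dof(f"hip_flexion_{side}", _Z, -1.6, 1.6),
                    _dof(f"hip_adduction_{side}", _X, -0.6, 0.6),
                    _dof(f"hip_rotation_{side}", _Y, -0.6, 0.6),
                ],
            )
        )
        joints.append(
            _joint(
                f"knee_{side}",
                fem,
                tib,
                (0.0, -0.40, 0.0),
                [_dof(f"knee_flexion_{side}", _Z, -2.1, 0.0)],
                t_child=(0.0, 0.02, 0.0),
            )
        )
        joints.append(
            _joint(
                f"ankle_{side}",
                tib,
                foot,
                (0.0, -0.43, 0.0),
                [
                    _dof(f"ankle_flexion_{side}", _X, -0.7, 0.7),
                    _dof(f"ankle_inversion_{side}", _Z, -0.5, 0.5),
                ],
            )
        )
        markers += _limb_markers(fem, 0.40, 0.05, 0.05)
        markers += _limb_markers(tib, 0.43, 0.045, 0.045)
        markers += _markers_for_body(
            foot,
            x_pair=((0.04, -0.04, 0.08), (-0.04, -0.04, 0.08)),
            y_pair=((0.0, 0.0, 0.08), (0.0, -0.08, 0.08)),
            z_pair=((0.0, -0.04, 0.20), (0.0, -0.04, -0.05)),
            bony_axis="z",
        )

    root_joint = JointDefinition(
        name="ground_pelvis",
        parent_body=GROUND,
        child_body="pelvis",
        orientation_in_parent=np.zeros(3),
        translation_in_parent=np.zeros(3),
        orientation_in_child=np.zeros(3),
        translation_in_child=np.zeros(3),
        dofs=[
            _dof("pelvis_tilt", _Z, -_INF, _INF),
            _dof("pelvis_list", _X, -_INF, _INF),
            _dof("pelvis_rotation", _Y, -_INF, _INF),
        ],
    )
    model = SkeletalModel(
        root_body="pelvis",
        bodies=bodies,
        joints=joints,
        markers=markers,
        root_joint=root_joint,
        name=f"default_humanoid_spine{n_sp}",
    )
    return model.validate()


def default_scale_config(model: SkeletalModel) -> ScalePairConfig:
    """One marker pair per body axis, following the fixture's naming convention."""
    pairs: dict[str, list[tuple[str, str, str]]] = {}
    marker_names = set(model.marker_names)
    for body in model.body_names:
        records = []
        for axis in ("x", "y", "z"):
            a, b = f"{body}_{axis}p", f"{body}_{axis}m"
            if a in marker_names and b in marker_names:
                records.append((a, b, axis))
        if records:
            pairs[body] = records
    return ScalePairConfig(pairs).validate(model)


# ---------------------------------------------------------------------------
# Motion simulation
# ---------------------------------------------------------------------------


def _draw_bank(rng, half_range, spec: TrajectorySpec):
    amps = rng.uniform(0.3, 1.0, spec.n_harmonics)
    amps = amps / amps.sum() * spec.amplitude_fraction * half_range
    freqs = rng.uniform(*spec.freq_range, spec.n_harmonics)
    phases = rng.uniform(0.0, 2 * np.pi, spec.n_harmonics)
    return list(zip(amps, freqs, phases))


def _eval_bank(bank, mean, t):
    out = np.full(len(t), mean)
    for a, f, phi in bank:
        out = out + a * np.sin(2 * np.pi * f * t + phi)
    return out


def simulate_motion(model: SkeletalModel, spec: TrajectorySpec | None = None) -> MotionSequence:
    """Smooth joint-angle trajectories within ranges, plus a slow root rotation.

    Deterministic given ``spec.seed``; zero amplitudes yield the constant
    neutral pose.
    """
    from .kinematics import root_transform_from_angles

    spec = (spec or TrajectorySpec()).validate()
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration * spec.rate))
    t = np.arange(n_frames) / spec.rate
    # amplitude envelope: neutral during the hold, smoothstep up over the ramp
    if spec.hold_s > 0 or spec.ramp_s > 0:
        u = np.clip((t - spec.hold_s) / max(spec.ramp_s, 1e-9), 0.0, 1.0)
        envelope = u * u * (3.0 - 2.0 * u)
    else:
        envelope = np.ones(n_frames)
    names = model.coordinate_names
    ranges = model.coordinate_ranges()
    means = neutral_angles(model)
    angles = np.empty((n_frames, len(names)))
    bank_cfg = spec.bank or {}
    for c, name in enumerate(names):
        lo, hi = ranges[c]
        half = (hi - lo) / 2.0 if np.isfinite(hi - lo) else 0.5
        bank = bank_cfg.get(name)
        if bank is None:
            bank = _draw_bank(rng, half, spec)
        else:
            if any(2 * f >= spec.rate for _, f, _ in bank):
                raise ValueError(f"bank frequency for {name} violates the sampling rate")
        angles[:, c] = means[c] + envelope * (_eval_bank(bank, means[c], t) - means[c])

    root_names = model.root_coordinate_names
    root_angles = np.zeros((n_frames, len(root_names)))
    for i, name in enumerate(root_names):
        bank = bank_cfg.get(name)
        if bank is None:
            a = spec.root_amplitude
            f = rng.uniform(*spec.root_freq_range)
            phi = rng.uniform(0.0, 2 * np.pi)
            bank = [(a, f, phi)]
        root_angles[:, i] = envelope * _eval_bank(bank, 0.0, t)
    if model.root_joint is not None and len(root_names):
        roots = np.stack(
            [
                root_transform_from_angles(model.root_joint, root_angles[f])[:3, :3]
                for f in range(n_frames)
            ]
        )
    else:
        roots = np.broadcast_to(np.eye(3), (n_frames, 3, 3)).copy()
    return MotionSequence(list(names), t, angles, roots).validate()


# ---------------------------------------------------------------------------
# Marker corruption
# ---------------------------------------------------------------------------


def corrupt_markers(true: MarkerTrajectory, spec: NoiseSpec | None = None) -> MarkerTrajectory:
    """Observed markers: truth + constant per-marker bias + Gaussian jitter + gaps.

    The bias direction is uniform on the sphere and its norm uniform in
    ``bias_norm_range``; it is exactly constant over time per marker.
    Occlusion gaps are ``occlusion_window``-frame windows whose starts are
    drawn so the expected occluded fraction matches ``occlusion_rate``.
    Deterministic given ``spec.seed``.
    """
    spec = (spec or NoiseSpec()).validate()
    rng = np.random.default_rng(spec.seed)
    F, M = true.n_frames, len(true.marker_names)
    direction = rng.normal(size=(M, 3))
    norms = np.linalg.norm(direction, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    direction /= norms
    bias = direction * rng.uniform(*spec.bias_norm_range, size=(M, 1))
    jitter = rng.normal(scale=spec.gaussian_sigma, size=(F, M, 3)) if spec.gaussian_sigma else 0.0
    positions = true.positions + bias[None, :, :] + jitter
    missing = true.missing.copy()
    if spec.occlusion_rate > 0:
        if spec.occlusion_rate >= 1.0:
            missing[:] = True
        else:
            p_start = min(1.0, spec.occlusion_rate / spec.occlusion_window)
            starts = rng.random((F, M)) < p_start
            occluded = np.zeros((F, M), dtype=bool)
            for k in range(spec.occlusion_window):
                occluded[k:] |= starts[: F - k if k else F]
            missing |= occluded
    return MarkerTrajectory(list(true.marker_names), true.timestamps.copy(), positions, missing)
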