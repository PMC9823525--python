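"""Skeletal-model schema and the motion-capture file formats the toolkit touches.

A skeletal model is a tree of rigid body segments connected by joints with up
to three rotational degrees of freedom each, plus markers rigidly attached to
bodies at fixed body-frame offsets.  Marker trajectories travel in TRC files,
joint-angle (generalized-coordinate) trajectories in MOT/STO files, and the
model itself in a structured YAML document.

Internal units are meters and radians everywhere; millimeters and degrees
appear only at file boundaries and in reports.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "GROUND",
    "ModelParseError",
    "ModelStructureError",
    "FileFormatError",
    "DegreeOfFreedom",
    "BodyDefinition",
    "JointDefinition",
    "MarkerDefinition",
    "SkeletalModel",
    "MarkerTrajectory",
    "MotionSequence",
    "read_model",
    "write_model",
    "read_trc",
    "write_trc",
    "read_mot",
    "write_mot",
]

#: Reserved parent-body name of the root (ground-to-pelvis) joint.
GROUND = "ground"

_AXIS_UNIT_TOL = 1e-9
_TIME_UNIFORM_TOL = 1e-6
_ROT_TOL = 1e-8


class ModelParseError(ValueError):
    """A model document violates the schema (bad or missing field)."""


class ModelStructureError(ValueError):
    """A model violates a structural invariant (cycle, bad axis, duplicate)."""


class FileFormatError(ValueError):
    """A TRC/MOT file is malformed (header/body mismatch, bad units)."""


def _as_vec3(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise ModelParseError(f"{name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ModelParseError(f"{name} must be finite")
    return arr


@dataclass
class DegreeOfFreedom:
    """One rotational coordinate of a joint: a named angle about a unit axis."""

    coordinate_name: str
    axis: np.ndarray  # unit 3-vector in the joint frame
    range: tuple[float, float] = (-math.pi, math.pi)  # rad, may be +-inf

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.range = (float(self.range[0]), float(self.range[1]))


@dataclass
class BodyDefinition:
    """A rigid segment.

    ``reference_length`` is the length in mm of the body's longest dimension
    in the default model; it converts unitless scale errors to millimeters.
    ``long_axis`` names which local axis (0=x, 1=y, 2=z) that dimension lies
    along.
    """

    name: str
    reference_length: float  # mm
    long_axis: int = 1


@dataclass
class JointDefinition:
    """A joint connecting ``parent_body`` to ``child_body``.

    The joint frame is placed at Euler orientation ``orientation_in_parent``
    and translation ``translation_in_parent`` in the parent frame, and at
    ``orientation_in_child`` / ``translation_in_child`` in the child frame.
    The motion between the two frames is a sequence of up to three axis-angle
    rotations (``dofs``).
    """

    name: str
    parent_body: str
    child_body: str
    orientation_in_parent: np.ndarray  # Euler angles, rad
    translation_in_parent: np.ndarray  # m (default-model frame)
    orientation_in_child: np.ndarray
    translation_in_child: np.ndarray
    dofs: list[DegreeOfFreedom] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.orientation_in_parent = _as_vec3(self.orientation_in_parent, f"{self.name}.orientation_in_parent")
        self.translation_in_parent = _as_vec3(self.translation_in_parent, f"{self.name}.translation_in_parent")
        self.orientation_in_child = _as_vec3(self.orientation_in_child, f"{self.name}.orientation_in_child")
        self.translation_in_child = _as_vec3(self.translation_in_child, f"{self.name}.translation_in_child")


@dataclass
class MarkerDefinition:
    """A point rigidly attached to ``anchor_body`` at body-frame offset (m)."""

    name: str
    anchor_body: str
    offset: np.ndarray  # m, body frame, default model
    is_bony_landmark: bool = False
    ik_weight: float = 1.0

    def __post_init__(self) -> None:
        self.offset = _as_vec3(self.offset, f"marker {self.name}.offset")


@dataclass
class SkeletalModel:
    """Tree of bodies, joints and markers rooted at ``root_body`` (pelvis analog).

    ``root_joint`` optionally describes the ground-to-root joint whose (up to
    three, unbounded) coordinates parameterise the root rotation; its parent
    body is the reserved name ``"ground"`` and it is not part of the body tree.
    """

    root_body: str
    bodies: list[BodyDefinition]
    joints: list[JointDefinition]
    markers: list[MarkerDefinition]
    root_joint: JointDefinition | None = None
    name: str = "model"

    # ---- derived helpers -------------------------------------------------

    @property
    def body_names(self) -> list[str]:
        return [b.name for b in self.bodies]

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def body_index(self, name: str) -> int:
        try:
            return self.body_names.index(name)
        except ValueError:
            raise ModelStructureError(f"unknown body {name!r}") from None

    def body(self, name: str) -> BodyDefinition:
        return self.bodies[self.body_index(name)]

    def level_order_joints(self) -> list[JointDefinition]:
        """Joints in deterministic breadth-first order from the root body."""
        by_parent: dict[str, list[JointDefinition]] = {}
        for j in self.joints:
            by_parent.setdefault(j.parent_body, []).append(j)
        order: list[JointDefinition] = []
        queue = [self.root_body]
        while queue:
            body = queue.pop(0)
            for j in by_parent.get(body, []):
                order.append(j)
                queue.append(j.child_body)
        return order

    @property
    def coordinate_names(self) -> list[str]:
        """Non-root coordinate names in level order."""
        return [d.coordinate_name for j in self.level_order_joints() for d in j.dofs]

    @property
    def root_coordinate_names(self) -> list[str]:
        if self.root_joint is None:
            return []
        return [d.coordinate_name for d in self.root_joint.dofs]

    def coordinate_ranges(self) -> np.ndarray:
        """(C, 2) array of [min, max] bounds for the non-root coordinates."""
        return np.array(
            [d.range for j in self.level_order_joints() for d in j.dofs], dtype=float
        ).reshape(-1, 2)

    # ---- validation ------------------------------------------------------

    def validate(self) -> "SkeletalModel":
        names = self.body_names
        if len(set(names)) != len(names):
            raise ModelStructureError("duplicate body names")
        for b in self.bodies:
            if not (b.reference_length > 0):
                raise ModelParseError(f"body {b.name}: reference_length must be > 0")
            if b.long_axis not in (0, 1, 2):
                raise ModelParseError(f"body {b.name}: long_axis must be 0, 1 or 2")
        if self.root_body not in names:
            raise ModelStructureError(f"root body {self.root_body!r} not defined")

        seen_coords: set[str] = set()
        all_joints = list(self.joints)
        if self.root_joint is not None:
            rj = self.root_joint
            if rj.parent_body != GROUND:
                raise ModelStructureError("root joint parent must be 'ground'")
            if rj.child_body != self.root_body:
                raise ModelStructureError("root joint child must be the root body")
            all_joints.append(rj)
        child_count: dict[str, int] = {n: 0 for n in names}
        for j in self.joints:
            for side in (j.parent_body, j.child_body):
                if side not in names:
                    raise ModelStructureError(f"joint {j.name}: unknown body {side!r}")
            child_count[j.child_body] += 1
        for j in all_joints:
            if len(j.dofs) > 3:
                raise ModelStructureError(f"joint {j.name}: more than 3 dofs")
            for d in j.dofs:
                if abs(np.linalg.norm(d.axis) - 1.0) > _AXIS_UNIT_TOL:
                    raise ModelStructureError(
                        f"joint {j.name}: axis of {d.coordinate_name!r} is not unit "
                        f"(norm {np.linalg.norm(d.axis):.6g})"
                    )
                if d.coordinate_name in seen_coords:
                    raise ModelStructureError(f"duplicate coordinate {d.coordinate_name!r}")
                seen_coords.add(d.coordinate_name)
                if not d.range[0] <= d.range[1]:
                    raise ModelParseError(f"coordinate {d.coordinate_name}: empty range")
        for body, count in child_count.items():
            if body == self.root_body:
                if count != 0:
                    raise ModelStructureError("root body may not be the child of a joint")
            elif count != 1:
                raise ModelStructureError(
                    f"body {body!r} must be the child of exactly one joint (found {count})"
                )
        # connectivity: BFS must reach every body (also rules out cycles)
        reached = {self.root_body} | {j.child_body for j in self.level_order_joints()}
        if reached != set(names):
            missing = sorted(set(names) - reached)
            raise ModelStructureError(f"bodies unreachable from root: {missing}")
        if len(self.level_order_joints()) != len(self.joints):
            raise ModelStructureError("joint graph is not a tree")

        marker_names = self.marker_names
        if len(set(marker_names)) != len(marker_names):
            raise ModelStructureError("duplicate marker names")
        for m in self.markers:
            if m.anchor_body not in names:
                raise ModelStructureError(f"marker {m.name}: unknown anchor body {m.anchor_body!r}")
            if m.ik_weight < 0:
                raise ModelParseError(f"marker {m.name}: ik_weight must be >= 0")
        return self


# ---------------------------------------------------------------------------
# Trajectory containers
# ---------------------------------------------------------------------------


def _check_uniform_time(timestamps: np.ndarray) -> None:
    if timestamps.ndim != 1:
        raise ValueError("timestamps must be 1-D")
    if len(timestamps) >= 2:
        dt = np.diff(timestamps)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > _TIME_UNIFORM_TOL:
            raise ValueError("timestamps must be uniformly spaced (within 1e-6 s)")


@dataclass
class MarkerTrajectory:
    """Per-frame 3D marker observations (m) with missing-data flags."""

    marker_names: list[str]
    timestamps: np.ndarray  # (F,), s
    positions: np.ndarray  # (F, M, 3), m
    missing: np.ndarray  # (F, M), bool

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            raise ValueError("need at least two frames for a time step")
        return float(self.timestamps[1] - self.timestamps[0])

    def validate(self) -> "MarkerTrajectory":
        _check_uniform_time(self.timestamps)
        F, M = self.n_frames, len(self.marker_names)
        if self.positions.shape != (F, M, 3):
            raise ValueError(f"positions shape {self.positions.shape} != {(F, M, 3)}")
        if self.missing.shape != (F, M):
            raise ValueError(f"missing shape {self.missing.shape} != {(F, M)}")
        if not np.all(np.isfinite(self.positions[~self.missing])):
            raise ValueError("non-missing positions must be finite")
        return self


@dataclass
class MotionSequence:
    """Uniformly sampled joint-angle frames plus a root rotation per frame.

    ``angles`` are radians; ``root_rotation`` holds the ground-from-pelvis
    rotation matrix per frame; ``valid`` flags carry the IK rejection rule
    (angles may be finite even where flagged invalid).
    """

    coordinate_names: list[str]
    timestamps: np.ndarray  # (F,), s
    angles: np.ndarray  # (F, C), rad
    root_rotation: np.ndarray  # (F, 3, 3)
    valid: np.ndarray | None = None  # (F, C), bool; default all-valid

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        self.root_rotation = np.asarray(self.root_rotation, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.angles.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            raise ValueError("need at least two frames for a time step")
        return float(self.timestamps[1] - self.timestamps[0])

    def validate(self) -> "MotionSequence":
        _check_uniform_time(self.timestamps)
        F, C = self.n_frames, len(self.coordinate_names)
        if self.angles.shape != (F, C):
            raise ValueError(f"angles shape {self.angles.shape} != {(F, C)}")
        if self.root_rotation.shape != (F, 3, 3):
            raise ValueError(f"root_rotation shape {self.root_rotation.shape} != {(F, 3, 3)}")
        if self.valid.shape != (F, C):
            raise ValueError(f"valid shape {self.valid.shape} != {(F, C)}")
        if not np.all(np.isfinite(self.angles[self.valid])):
            raise ValueError("angles must be finite where valid")
        for i, R in enumerate(self.root_rotation):
            if (np.max(np.abs(R.T @ R - np.eye(3))) > _ROT_TOL
                    or abs(np.linalg.det(R) - 1.0) > _ROT_TOL):
                raise ValueError(f"root rotation of frame {i} is not a proper rotation")
        return self


# ---------------------------------------------------------------------------
# Model schema (YAML)
# ---------------------------------------------------------------------------


def _model_to_dict(model: SkeletalModel) -> dict:
    def joint_dict(j: JointDefinition) -> dict:
        return {
            "name": j.name,
            "parent_body": j.parent_body,
            "child_body": j.child_body,
            "orientation_in_parent": [float(v) for v in j.orientation_in_parent],
            "translation_in_parent": [float(v) for v in j.translation_in_parent],
            "orientation_in_child": [float(v) for v in j.orientation_in_child],
            "translation_in_child": [float(v) for v in j.translation_in_child],
            "dofs": [
                {
                    "coordinate": d.coordinate_name,
                    "axis": [float(v) for v in d.axis],
                    "range": [float(d.range[0]), float(d.range[1])],
                }
                for d in j.dofs
            ],
        }

    doc = {
        "skelkin_model": 1,
        "name": model.name,
        "root_body": model.root_body,
        "bodies": [
            {"name": b.name, "reference_length_mm": float(b.reference_length), "long_axis": int(b.long_axis)}
            for b in model.bodies
        ],
        "joints": [joint_dict(j) for j in model.joints],
        "markers": [
            {
                "name": m.name,
                "body": m.anchor_body,
                "offset": [float(v) for v in m.offset],
                "bony_landmark": bool(m.is_bony_landmark),
                "ik_weight": float(m.ik_weight),
            }
            for m in model.markers
        ],
    }
    if model.root_joint is not None:
        doc["root_joint"] = joint_dict(model.root_joint)
    return doc


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ModelParseError(f"{context}: missing field {key!r}")
    return mapping[key]


def _joint_from_dict(d: dict) -> JointDefinition:
    name = _require(d, "name", "joint")
    dofs = []
    for rec in d.get("dofs", []):
        dofs.append(
            DegreeOfFreedom(
                coordinate_name=_require(rec, "coordinate", f"joint {name} dof"),
                axis=np.asarray(_require(rec, "axis", f"joint {name} dof"), dtype=float),
                range=tuple(rec.get("range", (-math.pi, math.pi))),
            )
        )
    return JointDefinition(
        name=name,
        parent_body=_require(d, "parent_body", f"joint {name}"),
        child_body=_require(d, "child_body", f"joint {name}"),
        orientation_in_parent=_require(d, "orientation_in_parent", f"joint {name}"),
        translation_in_parent=_require(d, "translation_in_parent", f"joint {name}"),
        orientation_in_child=_require(d, "orientation_in_child", f"joint {name}"),
        translation_in_child=_require(d, "translation_in_child", f"joint {name}"),
        dofs=dofs,
    )


def read_model(path: str | Path) -> SkeletalModel:
    """Read and validate a skeletal model from its YAML schema document."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ModelParseError(f"not a valid model document: {exc}") from exc
    if not isinstance(doc, dict) or "skelkin_model" not in doc:
        raise ModelParseError("not a skelkin model document (missing 'skelkin_model' key)")
    bodies = [
        BodyDefinition(
            name=_require(b, "name", "body"),
            reference_length=float(_require(b, "reference_length_mm", f"body {b.get('name')}")),
            long_axis=int(b.get("long_axis", 1)),
        )
        for b in _require(doc, "bodies", "model")
    ]
    joints = [_joint_from_dict(j) for j in _require(doc, "joints", "model")]
    markers = [
        MarkerDefinition(
            name=_require(m, "name", "marker"),
            anchor_body=_require(m, "body", f"marker {m.get('name')}"),
            offset=np.asarray(_require(m, "offset", f"marker {m.get('name')}"), dtype=float),
            is_bony_landmark=bool(m.get("bony_landmark", False)),
            ik_weight=float(m.get("ik_weight", 1.0)),
        )
        for m in doc.get("markers", [])
    ]
    root_joint = _joint_from_dict(doc["root_joint"]) if "root_joint" in doc else None
    model = SkeletalModel(
        root_body=_require(doc, "root_body", "model"),
        bodies=bodies,
        joints=joints,
        markers=markers,
        root_joint=root_joint,
        name=doc.get("name", "model"),
    )
    return model.validate()


def write_model(model: SkeletalModel, path: str | Path) -> None:
    """Write a validated model to its YAML schema document (lossless)."""
    model.validate()
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_model_to_dict(model), fh, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# TRC (marker trajectories)
# ---------------------------------------------------------------------------


def read_trc(path: str | Path) -> MarkerTrajectory:
    """Read a tab-separated TRC file; positions are converted to meters.

    Units may be ``mm`` or ``m`` (header field); blank cells become
    ``missing=True``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 5:
        raise FileFormatError("TRC file too short")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    header = dict(zip(header_keys, header_vals))
    try:
        n_frames = int(header["NumFrames"])
        n_markers = int(header["NumMarkers"])
        units = header["Units"].strip()
    except KeyError as exc:
        raise FileFormatError(f"TRC header missing {exc}") from exc
    if units == "mm":
        to_m = 1e-3
    elif units == "m":
        to_m = 1.0
    else:
        raise FileFormatError(f"unsupported TRC units {units!r}")
    names = [f for f in lines[3].split("\t")[2:] if f.strip()]
    if len(names) != n_markers:
        raise FileFormatError(
            f"TRC header declares {n_markers} markers but names row lists {len(names)}"
        )
    n_cols = 2 + 3 * n_markers
    data_lines = [ln for ln in lines[5:] if ln.strip()]
    if len(data_lines) != n_frames:
        raise FileFormatError(
            f"TRC header declares {n_frames} frames but file has {len(data_lines)} data rows"
        )
    times = np.empty(n_frames)
    positions = np.full((n_frames, n_markers, 3), np.nan)
    missing = np.zeros((n_frames, n_markers), dtype=bool)
    for i, ln in enumerate(data_lines):
        cells = ln.split("\t")
        if len(cells) < n_cols:
            cells = cells + [""] * (n_cols - len(cells))  # trailing blanks may be trimmed
        elif len(cells) > n_cols:
            raise FileFormatError(f"TRC row {i + 1}: {len(cells)} columns, expected {n_cols}")
        times[i] = float(cells[1])
        for m in range(n_markers):
            triple = cells[2 + 3 * m : 5 + 3 * m]
            if any(c.strip() == "" for c in triple):
                missing[i, m] = True
            else:
                positions[i, m] = [float(c) * to_m for c in triple]
    traj = MarkerTrajectory(names, times, positions, missing)
    return traj.validate()


def write_trc(traj: MarkerTrajectory, path: str | Path, units: str = "mm") -> None:
    """Write a MarkerTrajectory as TRC; missing markers become blank cells."""
    traj.validate()
    if units == "mm":
        scale = 1e3
    elif units == "m":
        scale = 1.0
    else:
        raise FileFormatError(f"unsupported TRC units {units!r}")
    F, M = traj.n_frames, len(traj.marker_names)
    rate = 1.0 / traj.dt if F >= 2 else 0.0
    buf = io.StringIO()
    buf.write(f"PathFileType\t4\t(X/Y/Z)\t{Path(path).name}\n")
    buf.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
    buf.write(f"{rate:.10g}\t{rate:.10g}\t{F}\t{M}\t{units}\t{rate:.10g}\t1\t{F}\n")
    buf.write("Frame#\tTime\t" + "\t\t\t".join(traj.marker_names) + "\t\t\n")
    buf.write("\t\t" + "\t".join(f"X{m + 1}\tY{m + 1}\tZ{m + 1}" for m in range(M)) + "\n")
    for i in range(F):
        cells = [str(i + 1), f"{traj.timestamps[i]:.10g}"]
        for m in range(M):
            if traj.missing[i, m]:
                cells += ["", "", ""]
            else:
                cells += [f"{v * scale:.10g}" for v in traj.positions[i, m]]
        buf.write("\t".join(cells) + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# MOT / STO (joint-angle trajectories)
# ---------------------------------------------------------------------------

_ROOT_COLS = [f"root_r{i}{j}" for i in range(3) for j in range(3)]


def read_mot(path: str | Path) -> MotionSequence:
    """Read a MOT/STO file: degrees on disk, radians in memory.

    The root rotation matrix is carried as nine auxiliary row-major columns
    ``root_r00 .. root_r22`` (unitless); if absent, identity is assumed.
    NaN angle cells are read back as invalid entries.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    header: dict[str, str] = {}
    i = 0
    for i, ln in enumerate(lines):
        if ln.strip().lower() == "endheader":
            break
        if "=" in ln:
            key, _, val = ln.partition("=")
            header[key.strip()] = val.strip()
    else:
        raise FileFormatError("MOT file has no 'endheader' line")
    in_degrees = header.get("inDegrees", "yes").lower() in ("yes", "true", "1")
    columns = lines[i + 1].split("\t")
    if not columns or columns[0] != "time":
        raise FileFormatError("MOT column header must start with 'time'")
    data_lines = [ln for ln in lines[i + 2 :] if ln.strip()]
    n_cols = len(columns)
    values = np.empty((len(data_lines), n_cols))
    for r, ln in enumerate(data_lines):
        cells = ln.split("\t")
        if len(cells) != n_cols:
            raise FileFormatError(f"MOT row {r + 1}: {len(cells)} columns, expected {n_cols}")
        values[r] = [float(c) if c.strip().lower() != "nan" else np.nan for c in cells]
    has_root = all(c in columns for c in _ROOT_COLS)
    coord_cols = [c for c in columns[1:] if c not in _ROOT_COLS]
    coord_idx = [columns.index(c) for c in coord_cols]
    F = len(data_lines)
    times = values[:, 0] if F else np.empty(0)
    angles = values[:, coord_idx] if F else np.empty((0, len(coord_cols)))
    if in_degrees:
        angles = np.deg2rad(angles)
    if has_root and F:
        root = values[:, [columns.index(c) for c in _ROOT_COLS]].reshape(F, 3, 3)
    else:
        root = np.broadcast_to(np.eye(3), (F, 3, 3)).copy()
    valid = np.isfinite(angles)
    angles = np.where(valid, angles, 0.0)
    seq = MotionSequence(coord_cols, times, angles, root, valid)
    return seq.validate()


def write_mot(seq: MotionSequence, path: str | Path, name: str = "skelkin motion") -> None:
    """Write a MotionSequence as MOT (degrees on disk, NaN where invalid)."""
    seq.validate()
    F, C = seq.n_frames, len(seq.coordinate_names)
    columns = ["time"] + list(seq.coordinate_names) + _ROOT_COLS
    buf = io.StringIO()
    buf.write(f"{name}\nversion=1\nnRows={F}\nnColumns={len(columns)}\ninDegrees=yes\nendheader\n")
    buf.write("\t".join(columns) + "\n")
    deg = np.rad2deg(seq.angles)
    for i in range(F):
        cells = [f"{seq.timestamps[i]:.10g}"]
        for c in range(C):
            cells.append(f"{deg[i, c]:.12g}" if seq.valid[i, c] else "nan")
        cells += [f"{v:.17g}" for v in seq.root_rotation[i].ravel()]
        buf.write("\t".join(cells) + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
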