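"""The skeletal-model layer: scaling-aware forward kinematics with gradients.

Given per-body scale factors ``beta`` (relative to an all-ones default), joint
angles ``theta`` and a ground-from-pelvis root rotation, the layer computes
world-frame (root-relative) positions of every body, joint and marker by
traversing the kinematic tree in level order:

* each joint's motion is a sequence of up to three axis-angle rotations, where
  each later axis is pre-rotated by the accumulated earlier rotations;
* joint frames sit at fixed Euler orientations and scale-dependent
  translations in the parent and child body frames;
* marker offsets scale elementwise with their anchor body's factors.

Every operation is a composition of smooth primitives; `fk_jacobian` exposes
the exact analytic derivatives of all marker (and joint) coordinates with
respect to the joint angles and body scales, which is what both gradient
training through the layer and damped least-squares inverse kinematics
consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model_io import DegreeOfFreedom, JointDefinition, SkeletalModel

__all__ = [
    "JointRangeWarning",
    "BodyScales",
    "PoseFrame",
    "axis_angle_matrix",
    "euler_to_matrix",
    "scale_translation",
    "motion_transform",
    "joint_frame_transform",
    "parent_child_transform",
    "root_transform_from_angles",
    "project_to_rotation",
    "forward_kinematics",
    "forward_kinematics_batch",
    "fk_jacobian",
    "rigid_transform",
    "angles_vector",
]

_AXIS_UNIT_TOL = 1e-9


class JointRangeWarning(UserWarning):
    """An angle fell outside its coordinate's declared range (not an error)."""


# ---------------------------------------------------------------------------
# Rotation primitives
# ---------------------------------------------------------------------------


def _skew(v: np.ndarray) -> np.ndarray:
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def axis_angle_matrix(axis, angle: float) -> np.ndarray:
    """Rotation by ``angle`` (rad, right-handed) about the unit 3-vector ``axis``.

    Rodrigues form ``R = cos(t) I + sin(t) [a]x + (1 - cos(t)) a a^T``.
    A non-unit axis is an error; there is no silent normalization.
    """
    a = np.asarray(axis, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"axis must be a 3-vector, got shape {a.shape}")
    if abs(np.linalg.norm(a) - 1.0) > _AXIS_UNIT_TOL:
        raise ValueError(f"axis must have unit norm, got {np.linalg.norm(a):.9g}")
    c, s = np.cos(angle), np.sin(angle)
    return c * np.eye(3) + s * _skew(a) + (1.0 - c) * np.outer(a, a)


def _rodrigues_batch(axis: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """(F, 3, 3) rotations about one fixed unit axis for F angles."""
    c = np.cos(angles)[:, None, None]
    s = np.sin(angles)[:, None, None]
    K = _skew(axis)
    return c * np.eye(3) + s * K + (1.0 - c) * np.outer(axis, axis)


def euler_to_matrix(euler) -> np.ndarray:
    """Euler angles (rad) to a rotation matrix.

    Convention (fixed, documented): intrinsic body-fixed rotations about X,
    then Y, then Z, i.e. ``R = Rx(o1) @ Ry(o2) @ Rz(o3)`` acting on column
    vectors — the convention of the musculoskeletal modeling software whose
    joint-frame orientations this schema mirrors.
    """
    o = np.asarray(euler, dtype=float)
    if o.shape != (3,):
        raise ValueError("euler angles must be a 3-vector")
    return (
        axis_angle_matrix((1.0, 0.0, 0.0), o[0])
        @ axis_angle_matrix((0.0, 1.0, 0.0), o[1])
        @ axis_angle_matrix((0.0, 0.0, 1.0), o[2])
    )


def project_to_rotation(M) -> np.ndarray:
    """Nearest rotation (Frobenius norm) to an arbitrary 3x3 matrix, det +1.

    Polar projection via SVD; useful when a regressor emits a raw 3x3 matrix
    as a continuous rotation representation.
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (3, 3):
        raise ValueError("expected a 3x3 matrix")
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix must be finite")
    U, _, Vt = np.linalg.svd(M)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


def rigid_transform(R=None, t=None) -> np.ndarray:
    """Assemble a 4x4 homogeneous transform from a rotation block and translation."""
    T = np.eye(4)
    if R is not None:
        T[:3, :3] = np.asarray(R, dtype=float)
    if t is not None:
        T[:3, 3] = np.asarray(t, dtype=float)
    return T


# ---------------------------------------------------------------------------
# Scaling and joint transforms
# ---------------------------------------------------------------------------


def scale_translation(T, beta_hat, beta=None) -> np.ndarray:
    """Scale a translation elementwise by the ratio of predicted to default scales.

    ``T_hat = T * (beta_hat / beta)``; ``beta`` defaults to all ones (the
    default model is the baseline).
    """
    T = np.asarray(T, dtype=float)
    bh = np.asarray(beta_hat, dtype=float)
    b = np.ones_like(bh) if beta is None else np.asarray(beta, dtype=float)
    if np.any(b <= 0):
        raise ValueError("default body scales must be strictly positive")
    return T * (bh / b)


def _range_check(dof: DegreeOfFreedom, value: float) -> None:
    lo, hi = dof.range
    if value < lo - 1e-12 or value > hi + 1e-12:
        warnings.warn("joint angle outside its declared coordinate range", JointRangeWarning)


def motion_transform(dofs, theta_values) -> np.ndarray:
    """Spatial motion of a joint as a 4x4 transform with zero translation.

    With ``R1 = G(A1, t1)``, ``R2 = G(R1 A2, t2)``, ``R3 = G(R2 R1 A3, t3)``
    (each later axis pre-rotated by the accumulated earlier rotations) the
    rotation block is ``R3 R2 R1``; absent degrees of freedom contribute the
    identity.  Angles outside a coordinate's declared range raise a
    `JointRangeWarning`, not an error.
    """
    theta = np.atleast_1d(np.asarray(theta_values, dtype=float))
    if len(theta) != len(dofs):
        raise ValueError(f"got {len(theta)} angles for {len(dofs)} dofs")
    accumulated = np.eye(3)
    rotations = []
    for dof, value in zip(dofs, theta):
        axis = np.asarray(getattr(dof, "axis", dof), dtype=float)
        if hasattr(dof, "range"):
            _range_check(dof, float(value))
        R = axis_angle_matrix(accumulated @ axis, float(value))
        rotations.append(R)
        accumulated = R @ accumulated
    out = np.eye(4)
    out[:3, :3] = accumulated  # = R3 @ R2 @ R1
    return out


def joint_frame_transform(euler, translation) -> np.ndarray:
    """Joint-frame placement: rotation block from Euler angles, given translation."""
    return rigid_transform(euler_to_matrix(euler), translation)


def _inv_rigid(T: np.ndarray) -> np.ndarray:
    R = T[:3, :3]
    out = np.eye(4)
    out[:3, :3] = R.T
    out[:3, 3] = -R.T @ T[:3, 3]
    return out


def parent_child_transform(
    joint: JointDefinition,
    theta_values,
    parent_ratio=None,
    child_ratio=None,
) -> np.ndarray:
    """Transform from the child body frame to the parent body frame.

    ``R_parent<-child = R_parent<-joint @ R_motion @ R_child<-joint^-1`` with
    the parent-side translation scaled by the parent body's scale ratio and
    the child-side translation by the child body's ratio (``beta_hat / beta``,
    default ones).
    """
    pr = np.ones(3) if parent_ratio is None else np.asarray(parent_ratio, dtype=float)
    cr = np.ones(3) if child_ratio is None else np.asarray(child_ratio, dtype=float)
    Tp_hat = scale_translation(joint.translation_in_parent, pr)
    Tc_hat = scale_translation(joint.translation_in_child, cr)
    A_parent = joint_frame_transform(joint.orientation_in_parent, Tp_hat)
    A_child = joint_frame_transform(joint.orientation_in_child, Tc_hat)
    return A_parent @ motion_transform(joint.dofs, theta_values) @ _inv_rigid(A_child)


def root_transform_from_angles(root_joint: JointDefinition, theta_values) -> np.ndarray:
    """Ground-from-pelvis transform from the root joint's (<=3) coordinates.

    ``R_ground<-pelvis = I @ R_motion @ R_pelvis<-joint^-1`` with the
    translation part zeroed: the layer predicts root-relative positions, so
    only the rotation matters.
    """
    A_child = joint_frame_transform(root_joint.orientation_in_child, root_joint.translation_in_child)
    out = np.eye(4) @ motion_transform(root_joint.dofs, theta_values) @ _inv_rigid(A_child)
    out[:3, 3] = 0.0
    return out


# ---------------------------------------------------------------------------
# Body scales
# ---------------------------------------------------------------------------


@dataclass
class BodyScales:
    """Per-body, per-axis positive scale factors relative to the default model.

    The default model's scales are the all-ones baseline, so ``values`` are
    directly the elementwise ratios applied to translations and marker
    offsets.
    """

    body_names: list[str]
    values: np.ndarray  # (B, 3), > 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.body_names), 3):
            raise ValueError("values must have shape (n_bodies, 3)")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("body scales must be finite and strictly positive")

    @classmethod
    def ones(cls, model: SkeletalModel) -> "BodyScales":
        return cls(list(model.body_names), np.ones((len(model.bodies), 3)))

    @classmethod
    def uniform(cls, model: SkeletalModel, factor: float) -> "BodyScales":
        return cls(list(model.body_names), np.full((len(model.bodies), 3), float(factor)))

    @classmethod
    def from_mapping(cls, model: SkeletalModel, mapping: dict) -> "BodyScales":
        values = np.ones((len(model.bodies), 3))
        for name, v in mapping.items():
            values[model.body_index(name)] = np.asarray(v, dtype=float)
        return cls(list(model.body_names), values)

    def for_body(self, name: str) -> np.ndarray:
        return self.values[self.body_names.index(name)]

    def aligned(self, model: SkeletalModel) -> np.ndarray:
        """(B, 3) values reordered to the model's body order."""
        if self.body_names == model.body_names:
            return self.values
        idx = [self.body_names.index(n) for n in model.body_names]
        return self.values[idx]

    def to_mapping(self) -> dict:
        return {n: [float(v) for v in row] for n, row in zip(self.body_names, self.values)}


# ---------------------------------------------------------------------------
# Compiled topology (cached per model instance)
# ---------------------------------------------------------------------------


@dataclass
class _JointInfo:
    name: str
    parent: int
    child: int
    R_op: np.ndarray  # F(O_parent)
    R_oc: np.ndarray  # F(O_child)
    T_p: np.ndarray
    T_c: np.ndarray
    axes: np.ndarray  # (D, 3)
    coord_idx: list[int]
    ranges: np.ndarray  # (D, 2)


@dataclass
class _Topology:
    body_names: list[str]
    root: int
    joints: list[_JointInfo]  # level order
    joint_child: np.ndarray  # (J,) child body index per level-order joint
    n_coords: int
    coordinate_names: list[str]
    coord_child: np.ndarray  # (C,) child body index of each coordinate's joint
    ranges: np.ndarray  # (C, 2)
    subtree: np.ndarray  # (B, B) bool; subtree[b] = bodies at/below b
    marker_anchor: np.ndarray  # (M,)
    marker_offsets: np.ndarray  # (M, 3)
    marker_names: list[str]
    coord_marker_mask: np.ndarray  # (C, M) bool: marker moved by coordinate
    coord_joint_mask: np.ndarray  # (C, J) bool: joint position moved by coordinate


def _topology(model: SkeletalModel) -> _Topology:
    cached = model.__dict__.get("_skelkin_topology")
    if cached is not None:
        return cached
    body_index = {n: i for i, n in enumerate(model.body_names)}
    level = model.level_order_joints()
    joints: list[_JointInfo] = []
    coord_names: list[str] = []
    coord_child: list[int] = []
    ranges: list[tuple[float, float]] = []
    for j in level:
        idx = []
        for d in j.dofs:
            idx.append(len(coord_names))
            coord_names.append(d.coordinate_name)
            coord_child.append(body_index[j.child_body])
            ranges.append(d.range)
        joints.append(
            _JointInfo(
                name=j.name,
                parent=body_index[j.parent_body],
                child=body_index[j.child_body],
                R_op=euler_to_matrix(j.orientation_in_parent),
                R_oc=euler_to_matrix(j.orientation_in_child),
                T_p=np.asarray(j.translation_in_parent, dtype=float),
                T_c=np.asarray(j.translation_in_child, dtype=float),
                axes=np.array([d.axis for d in j.dofs], dtype=float).reshape(-1, 3),
                coord_idx=idx,
                ranges=np.array([d.range for d in j.dofs], dtype=float).reshape(-1, 2),
            )
        )
    B = len(model.bodies)
    children: dict[int, list[int]] = {}
    for ji in joints:
        children.setdefault(ji.parent, []).append(ji.child)
    subtree = np.zeros((B, B), dtype=bool)
    # level-order joints guarantee parents precede children; fill bottom-up
    for b in range(B):
        stack = [b]
        while stack:
            cur = stack.pop()
            subtree[b, cur] = True
            stack.extend(children.get(cur, []))
    coord_child_arr = np.array(coord_child, dtype=int)
    marker_anchor = np.array([body_index[m.anchor_body] for m in model.markers], dtype=int)
    joint_child = np.array([ji.child for ji in joints], dtype=int)
    topo = _Topology(
        body_names=list(model.body_names),
        root=body_index[model.root_body],
        joints=joints,
        joint_child=joint_child,
        n_coords=len(coord_names),
        coordinate_names=coord_names,
        coord_child=coord_child_arr,
        ranges=np.array(ranges, dtype=float).reshape(-1, 2),
        subtree=subtree,
        marker_anchor=marker_anchor,
        marker_offsets=np.array([m.offset for m in model.markers], dtype=float).reshape(-1, 3),
        marker_names=list(model.marker_names),
        coord_marker_mask=subtree[np.ix_(coord_child_arr, marker_anchor)]
        if len(coord_child_arr) and len(marker_anchor)
        else np.zeros((len(coord_names), len(marker_anchor)), dtype=bool),
        coord_joint_mask=subtree[np.ix_(coord_child_arr, joint_child)]
        if len(coord_child_arr) and len(joint_child)
        else np.zeros((len(coord_names), len(joint_child)), dtype=bool),
    )
    model.__dict__["_skelkin_topology"] = topo
    return topo


def angles_vector(model: SkeletalModel, mapping) -> np.ndarray:
    """Order a {coordinate name: angle} mapping into the model's coordinate vector."""
    if isinstance(mapping, dict):
        names = model.coordinate_names
        missing = [n for n in names if n not in mapping]
        if missing:
            raise ValueError(f"missing coordinate values: {missing}")
        return np.array([mapping[n] for n in names], dtype=float)
    arr = np.asarray(mapping, dtype=float)
    if arr.shape != (len(model.coordinate_names),):
        raise ValueError(
            f"angle vector has shape {arr.shape}, expected ({len(model.coordinate_names)},)"
        )
    return arr


# ---------------------------------------------------------------------------
# Forward kinematics
# ---------------------------------------------------------------------------


@dataclass
class PoseFrame:
    """World (root-relative) transforms and positions for one frame."""

    body_names: list[str]
    world_transforms: np.ndarray  # (B, 4, 4)
    joint_names: list[str]
    joint_positions: np.ndarray  # (J, 3): world origin of each joint's child body
    marker_names: list[str]
    marker_positions: np.ndarray  # (M, 3)


@dataclass
class BatchPose:
    """Frame-wise FK results for a whole sequence."""

    rotations: np.ndarray  # (F, B, 3, 3)
    translations: np.ndarray  # (F, B, 3)
    joint_positions: np.ndarray  # (F, J, 3)
    marker_positions: np.ndarray  # (F, M, 3)


def _resolve_scales(model: SkeletalModel, scales) -> np.ndarray:
    if scales is None:
        return np.ones((len(model.bodies), 3))
    if isinstance(scales, BodyScales):
        return scales.aligned(model)
    arr = np.asarray(scales, dtype=float)
    if arr.shape != (len(model.bodies), 3):
        raise ValueError(f"scales shape {arr.shape} != ({len(model.bodies)}, 3)")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("body scales must be finite and strictly positive")
    return arr


def _resolve_roots(root, F: int) -> tuple[np.ndarray, np.ndarray]:
    if root is None:
        return np.broadcast_to(np.eye(3), (F, 3, 3)), np.zeros((F, 3))
    arr = np.asarray(root, dtype=float)
    if arr.shape in ((3, 3), (4, 4)):
        arr = np.broadcast_to(arr, (F,) + arr.shape)
    if arr.shape == (F, 3, 3):
        return arr, np.zeros((F, 3))
    if arr.shape == (F, 4, 4):
        return arr[:, :3, :3], arr[:, :3, 3]
    raise ValueError(f"unsupported root shape {arr.shape}")


def forward_kinematics_batch(model: SkeletalModel, scales, angles, root=None) -> BatchPose:
    """Level-order forward kinematics, vectorized over frames.

    ``angles`` is (F, C) ordered like ``model.coordinate_names``; ``root`` may
    be one or F rotation matrices / 4x4 transforms (identity by default).
    Frame-wise results are identical to per-frame `forward_kinematics` calls.
    """
    topo = _topology(model)
    ratios = _resolve_scales(model, scales)
    theta = np.asarray(angles, dtype=float)
    if theta.ndim != 2 or theta.shape[1] != topo.n_coords:
        raise ValueError(f"angles must be (F, {topo.n_coords}), got {theta.shape}")
    if not np.all(np.isfinite(theta)):
        raise ValueError("angles must be finite (invalid frames cannot enter FK)")
    F = theta.shape[0]
    if topo.n_coords and F and (
        np.any(theta < topo.ranges[:, 0] - 1e-12) or np.any(theta > topo.ranges[:, 1] + 1e-12)
    ):
        warnings.warn("joint angle outside its declared coordinate range", JointRangeWarning)
    R0, t0 = _resolve_roots(root, F)
    B = len(topo.body_names)
    Rw = np.zeros((F, B, 3, 3))
    tw = np.zeros((F, B, 3))
    Rw[:, topo.root] = R0
    tw[:, topo.root] = t0
    for ji in topo.joints:
        Rm = np.broadcast_to(np.eye(3), (F, 3, 3))
        for axis, ci in zip(ji.axes, ji.coord_idx):
            Rm = Rm @ _rodrigues_batch(axis, theta[:, ci])
        R_A = np.einsum("ij,fjk,lk->fil", ji.R_op, Rm, ji.R_oc)
        Tp_hat = ji.T_p * ratios[ji.parent]
        Tc_hat = ji.T_c * ratios[ji.child]
        t_A = Tp_hat - np.einsum("fij,j->fi", R_A, Tc_hat)
        Rw[:, ji.child] = Rw[:, ji.parent] @ R_A
        tw[:, ji.child] = tw[:, ji.parent] + np.einsum("fij,fj->fi", Rw[:, ji.parent], t_A)
    joint_positions = tw[:, topo.joint_child] if topo.joints else np.zeros((F, 0, 3))
    if len(topo.marker_anchor):
        d_hat = topo.marker_offsets * ratios[topo.marker_anchor]
        marker_positions = (
            np.einsum("fmij,mj->fmi", Rw[:, topo.marker_anchor], d_hat)
            + tw[:, topo.marker_anchor]
        )
    else:
        marker_positions = np.zeros((F, 0, 3))
    return BatchPose(Rw, tw, joint_positions, marker_positions)


def forward_kinematics(model: SkeletalModel, scales, angles, root=None) -> PoseFrame:
    """Forward kinematics for a single frame.

    ``angles`` supplies a value for every coordinate (vector in model order or
    a name-to-value mapping); ``scales`` covers every body (`BodyScales`,
    (B, 3) array, or None for the default model); ``root`` is the
    ground-from-pelvis transform (rotation only for root-relative output).
    """
    topo = _topology(model)
    theta = angles_vector(model, angles)
    batch = forward_kinematics_batch(model, scales, theta[None, :], root)
    B = len(topo.body_names)
    transforms = np.broadcast_to(np.eye(4), (B, 4, 4)).copy()
    transforms[:, :3, :3] = batch.rotations[0]
    transforms[:, :3, 3] = batch.translations[0]
    return PoseFrame(
        body_names=list(topo.body_names),
        world_transforms=transforms,
        joint_names=[ji.name for ji in topo.joints],
        joint_positions=batch.joint_positions[0],
        marker_names=list(topo.marker_names),
        marker_positions=batch.marker_positions[0],
    )


# ---------------------------------------------------------------------------
# Analytic Jacobians
# ---------------------------------------------------------------------------


@dataclass
class FrameDerivatives:
    """FK outputs and their exact partial derivatives for one frame.

    ``Jm_*`` differentiate marker positions, ``Jj_*`` joint positions; the
    ``theta`` blocks are (N, 3, C), the ``beta`` blocks (N, 3, B, 3), and the
    optional ``root`` blocks (N, 3, R) for the root joint's own coordinates.
    """

    marker_positions: np.ndarray
    joint_positions: np.ndarray
    rotations: np.ndarray  # (B, 3, 3)
    translations: np.ndarray  # (B, 3)
    Jm_theta: np.ndarray
    Jj_theta: np.ndarray | None
    Jm_beta: np.ndarray | None
    Jj_beta: np.ndarray | None
    Jm_root: np.ndarray | None = None
    Jj_root: np.ndarray | None = None


def _frame_derivatives(
    model: SkeletalModel,
    scales,
    angles,
    root=None,
    root_angles=None,
    need_beta: bool = True,
    need_joints: bool = True,
) -> FrameDerivatives:
    """One FK pass plus geometric derivatives.

    For a rotational coordinate the derivative of any downstream point p is
    ``omega x (p - c)`` with ``omega`` the coordinate's world-frame axis and
    ``c`` the world position of its joint frame; scale derivatives chain
    linearly through the scaled translations and marker offsets.  If
    ``root_angles`` is given (with a model root joint), the root transform is
    built from them and derivative columns for the root coordinates are
    included.
    """
    topo = _topology(model)
    ratios = _resolve_scales(model, scales)
    theta = angles_vector(model, angles)
    root_prefixes = None
    if root_angles is not None:
        if model.root_joint is None:
            raise ValueError("model has no root joint to parameterise")
        root_angles = np.atleast_1d(np.asarray(root_angles, dtype=float))
        root = root_transform_from_angles(model.root_joint, root_angles)
        # prefix rotations G1..G_{i-1} give each root coordinate's world axis
        root_prefixes = [np.eye(3)]
        for d, v in zip(model.root_joint.dofs, root_angles):
            root_prefixes.append(root_prefixes[-1] @ axis_angle_matrix(d.axis, float(v)))
    R0, t0 = _resolve_roots(root, 1)
    B = len(topo.body_names)
    C = topo.n_coords
    M = len(topo.marker_anchor)
    J = len(topo.joints)
    Rw = np.zeros((B, 3, 3))
    tw = np.zeros((B, 3))
    Rw[topo.root] = R0[0]
    tw[topo.root] = t0[0]
    omega = np.zeros((C, 3))
    pivot = np.zeros((C, 3))
    for ji in topo.joints:
        Tp_hat = ji.T_p * ratios[ji.parent]
        Tc_hat = ji.T_c * ratios[ji.child]
        joint_origin = tw[ji.parent] + Rw[ji.parent] @ Tp_hat
        prefix = Rw[ji.parent] @ ji.R_op  # accumulated frame before this joint's dofs
        Rm = np.eye(3)
        for axis, ci in zip(ji.axes, ji.coord_idx):
            omega[ci] = prefix @ Rm @ axis
            pivot[ci] = joint_origin
            Rm = Rm @ axis_angle_matrix(axis, theta[ci])
        R_A = ji.R_op @ Rm @ ji.R_oc.T
        Rw[ji.child] = Rw[ji.parent] @ R_A
        tw[ji.child] = tw[ji.parent] + Rw[ji.parent] @ (Tp_hat - R_A @ Tc_hat)
    joint_positions = tw[topo.joint_child] if J else np.zeros((0, 3))
    d_hat = topo.marker_offsets * ratios[topo.marker_anchor] if M else np.zeros((0, 3))
    marker_positions = (
        np.einsum("mij,mj->mi", Rw[topo.marker_anchor], d_hat) + tw[topo.marker_anchor]
        if M
        else np.zeros((0, 3))
    )

    # --- theta columns: omega x (p - c), masked to the coordinate's subtree
    Jm_theta = (
        np.cross(omega[:, None, :], marker_positions[None, :, :] - pivot[:, None, :])
        * topo.coord_marker_mask[:, :, None]
    ).transpose(1, 2, 0)  # (M, 3, C)
    Jj_theta = None
    if need_joints:
        Jj_theta = (
            np.cross(omega[:, None, :], joint_positions[None, :, :] - pivot[:, None, :])
            * topo.coord_joint_mask[:, :, None]
        ).transpose(1, 2, 0)

    # --- beta columns: linear chain through scaled translations and offsets
    Jm_beta = Jj_beta = None
    if need_beta:
        Jm_beta = np.zeros((M, 3, B, 3))
        Jj_beta = np.zeros((J, 3, B, 3))
        for ji in topo.joints:
            m_mask = topo.subtree[ji.child, topo.marker_anchor]
            j_mask = topo.subtree[ji.child, topo.joint_child]
            contrib_p = Rw[ji.parent] * ji.T_p  # (3, 3): column a is d t / d beta[parent, a]
            contrib_c = -Rw[ji.child] * ji.T_c
            Jm_beta[m_mask, :, ji.parent, :] += contrib_p
            Jm_beta[m_mask, :, ji.child, :] += contrib_c
            Jj_beta[j_mask, :, ji.parent, :] += contrib_p
            Jj_beta[j_mask, :, ji.child, :] += contrib_c
        if M:
            Jm_beta[np.arange(M), :, topo.marker_anchor, :] += (
                Rw[topo.marker_anchor] * topo.marker_offsets[:, None, :]
            )

    result = FrameDerivatives(
        marker_positions=marker_positions,
        joint_positions=joint_positions,
        rotations=Rw,
        translations=tw,
        Jm_theta=Jm_theta,
        Jj_theta=Jj_theta,
        Jm_beta=Jm_beta,
        Jj_beta=Jj_beta,
    )

    if root_prefixes is not None:
        Rn = len(model.root_joint.dofs)
        Jm_root = np.zeros((M, 3, Rn))
        Jj_root = np.zeros((J, 3, Rn))
        for i, d in enumerate(model.root_joint.dofs):
            w = root_prefixes[i] @ d.axis
            Jm_root[:, :, i] = np.cross(w, marker_positions - t0[0])
            Jj_root[:, :, i] = np.cross(w, joint_positions - t0[0])
        result.Jm_root = Jm_root
        result.Jj_root = Jj_root
    return result


def neutral_angles(model: SkeletalModel) -> np.ndarray:
    """A neutral pose: the midpoint of each coordinate's range (0 if unbounded)."""
    ranges = model.coordinate_ranges()
    mid = np.where(np.all(np.isfinite(ranges), axis=1), ranges.mean(axis=1), 0.0)
    return mid


def fk_jacobian(model: SkeletalModel, scales, angles, root=None) -> np.ndarray:
    """Exact Jacobian of all marker coordinates w.r.t. (theta, body scales).

    Rows are marker coordinates in marker-major order (x, y, z per marker);
    columns are the model's coordinates followed by the body-scale entries in
    body-major (x, y, z) order, giving a (3M, C + 3B) matrix.  Matches central
    finite differences of `forward_kinematics` to first order exactly.
    """
    d = _frame_derivatives(model, scales, angles, root=root)
    M = d.marker_positions.shape[0]
    C = d.Jm_theta.shape[2]
    B = d.Jm_beta.shape[2]
    return np.concatenate(
        [d.Jm_theta.reshape(3 * M, C), d.Jm_beta.reshape(3 * M, 3 * B)], axis=1
    )
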