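"""Model scaling and marker-based inverse kinematics (the multi-step baseline).

Scaling compares observed marker-pair distances during a calibration window
against the same distances on the default model and assigns the ratios to
body axes.  Inverse kinematics then moves the scaled model, frame by frame,
to the configuration minimizing the sum of weighted squared errors between
observed and model markers, using a damped Gauss-Newton (Levenberg-Marquardt
style) iteration with the analytic FK Jacobian.  Joint angles adjacent to any
segment whose marker RMS residual exceeds a threshold (default 20 mm) are
flagged invalid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .kinematics import (
    BodyScales,
    _frame_derivatives,
    forward_kinematics,
    forward_kinematics_batch,
    neutral_angles,
    root_transform_from_angles,
    _topology,
)
from .model_io import MarkerTrajectory, MotionSequence, SkeletalModel

__all__ = [
    "ScalePairConfig",
    "IKConfig",
    "IKFrameResult",
    "IKResult",
    "scale_from_markers",
    "solve_ik_frame",
    "solve_ik_sequence",
    "lowpass_smooth",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class ScalePairConfig:
    """Maps observed marker-pair distances to body axes.

    ``pairs`` maps a body name to records ``(marker_a, marker_b, axis)`` with
    axis one of ``"x" | "y" | "z"``.  Pairs should lie on a single body so
    their distance is pose-invariant; the default-model distance is measured
    on the neutral pose.
    """

    pairs: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)

    def validate(self, model: SkeletalModel) -> "ScalePairConfig":
        marker_names = set(model.marker_names)
        for body, records in self.pairs.items():
            model.body_index(body)  # raises on unknown body
            for a, b, axis in records:
                if a not in marker_names or b not in marker_names:
                    raise ValueError(f"scale pair ({a}, {b}) uses an unknown marker")
                if axis not in _AXES:
                    raise ValueError(f"axis must be x, y or z, got {axis!r}")
        return self


def scale_from_markers(
    model: SkeletalModel,
    calibration: MarkerTrajectory,
    cfg: ScalePairConfig,
) -> BodyScales:
    """Estimate per-body scale factors from calibration-frame marker distances.

    For each configured ``(marker_a, marker_b, axis)`` the scale is the mean
    observed distance over calibration frames (skipping frames where either
    marker is missing) divided by the default-model distance.  Unconfigured
    axes inherit the body's mean configured scale; bodies with no
    configuration inherit the mean of all configured scales (1.0 if none).
    """
    cfg.validate(model)
    midx = {n: i for i, n in enumerate(model.marker_names)}
    neutral = forward_kinematics(model, None, neutral_angles(model))
    default_pos = neutral.marker_positions
    values = np.full((len(model.bodies), 3), np.nan)
    all_scales: list[float] = []
    for body, records in cfg.pairs.items():
        b = model.body_index(body)
        for name_a, name_b, axis in records:
            ia, ib = midx[name_a], midx[name_b]
            model_dist = float(np.linalg.norm(default_pos[ia] - default_pos[ib]))
            if model_dist <= 1e-12:
                raise ValueError(f"zero default-model distance for pair ({name_a}, {name_b})")
            present = ~(calibration.missing[:, ia] | calibration.missing[:, ib])
            if not present.any():
                raise ValueError(
                    f"markers ({name_a}, {name_b}) are missing in every calibration frame"
                )
            obs = np.linalg.norm(
                calibration.positions[present, ia] - calibration.positions[present, ib], axis=-1
            )
            s = float(np.mean(obs)) / model_dist
            values[b, _AXES[axis]] = s
            all_scales.append(s)
    overall = float(np.mean(all_scales)) if all_scales else 1.0
    for b in range(values.shape[0]):
        configured = values[b][np.isfinite(values[b])]
        fallback = float(np.mean(configured)) if len(configured) else overall
        values[b] = np.where(np.isfinite(values[b]), values[b], fallback)
    return BodyScales(list(model.body_names), values)


# ---------------------------------------------------------------------------
# Inverse kinematics
# ---------------------------------------------------------------------------


@dataclass
class IKConfig:
    """Solver settings for weighted least-squares inverse kinematics."""

    max_iter: int = 100
    step_tol: float = 1e-8  # rad; stop when the update norm falls below
    cost_tol: float = 1e-4  # stop when the relative cost improvement falls below
    lm_lambda0: float = 1e-3
    reject_mm: float = 20.0  # per-segment marker RMS residual threshold
    smooth_cutoff_hz: float | None = None  # optional low-pass on solved angles


@dataclass
class IKFrameResult:
    """Solution of one frame: angles, root, residuals and solver diagnostics."""

    theta: np.ndarray  # (C,) rad
    root_angles: np.ndarray  # (R,) rad
    root_rotation: np.ndarray  # (3, 3)
    segment_rms: np.ndarray  # (B,) m; NaN for segments with no observed marker
    objective: float  # final weighted sum of squared errors (m^2)
    objective_trace: list  # objective after each accepted step (non-increasing)
    converged: bool
    n_iter: int


@dataclass
class IKResult:
    """Per-frame IK solutions for a trajectory, with the rejection rule applied."""

    motion: MotionSequence
    root_angles: np.ndarray  # (F, R)
    segment_rms: np.ndarray  # (F, B) m
    objective: np.ndarray  # (F,)
    converged: np.ndarray  # (F,) bool


def _marker_weights(model: SkeletalModel, weights) -> np.ndarray:
    if weights is None:
        return np.array([m.ik_weight for m in model.markers], dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(model.markers),):
        raise ValueError("weights must have one entry per model marker")
    if np.any(w < 0):
        raise ValueError("marker weights must be >= 0")
    return w


def _segment_rms(topo, fk_markers, observed, present) -> np.ndarray:
    B = len(topo.body_names)
    rms = np.full(B, np.nan)
    err = np.linalg.norm(fk_markers - observed, axis=-1)
    for b in range(B):
        sel = present & (topo.marker_anchor == b)
        if sel.any():
            rms[b] = np.sqrt(np.mean(err[sel] ** 2))
    return rms


def solve_ik_frame(
    model: SkeletalModel,
    scales: BodyScales | None,
    observed: np.ndarray,
    missing=None,
    weights=None,
    theta_init=None,
    root_angles_init=None,
    config: IKConfig | None = None,
) -> IKFrameResult:
    """Fit joint angles and root rotation of one frame to observed markers.

    Minimizes ``sum_m w_m ||obs_m - FK_m(theta)||^2`` over the model's
    coordinates plus the (unbounded) root-joint coordinates, by damped
    Gauss-Newton steps with the analytic Jacobian.  Missing markers are
    excluded; bounded coordinates are projected into their declared ranges
    after each accepted step.  On non-convergence the best iterate is
    returned with ``converged=False``.
    """
    config = config or IKConfig()
    topo = _topology(model)
    if model.root_joint is None:
        raise ValueError("IK requires a model with a root joint")
    C = topo.n_coords
    R = len(model.root_joint.dofs)
    observed = np.asarray(observed, dtype=float)
    M = len(model.markers)
    if observed.shape != (M, 3):
        raise ValueError(f"observed markers must be ({M}, 3)")
    present = np.ones(M, dtype=bool) if missing is None else ~np.asarray(missing, dtype=bool)
    w = _marker_weights(model, weights)
    present = present & (w > 0)
    if present.sum() * 3 < C + R:
        warnings.warn(
            "fewer observed marker coordinates than free coordinates; frame is under-constrained",
            stacklevel=2,
        )
    theta = neutral_angles(model) if theta_init is None else np.array(theta_init, dtype=float)
    q_root = np.zeros(R) if root_angles_init is None else np.array(root_angles_init, dtype=float)
    ranges = topo.ranges
    sw = np.sqrt(w[present])[:, None]

    def cost_only(q_root, theta):
        root = root_transform_from_angles(model.root_joint, q_root)
        pose = forward_kinematics_batch(model, scales, theta[None], root)
        diff = (pose.marker_positions[0][present] - observed[present]) * sw
        return float(np.sum(diff**2))

    def residual_and_jac(q_root, theta):
        d = _frame_derivatives(
            model, scales, theta, root_angles=q_root, need_beta=False, need_joints=False
        )
        diff = (d.marker_positions[present] - observed[present]) * sw
        cost = float(np.sum(diff**2))
        Jr = d.Jm_root[present] * sw[:, :, None]  # (Mo, 3, R)
        Jt = d.Jm_theta[present] * sw[:, :, None]  # (Mo, 3, C)
        n_obs = int(present.sum())
        J = np.concatenate(
            [Jr.reshape(3 * n_obs, R), Jt.reshape(3 * n_obs, C)], axis=1
        )
        return cost, diff.ravel(), J, d

    cost, r, J, deriv = residual_and_jac(q_root, theta)
    trace = [cost]
    lam = config.lm_lambda0
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        H = J.T @ J
        g = J.T @ r
        accepted = False
        for _ in range(12):
            try:
                delta = np.linalg.solve(H + lam * np.eye(H.shape[0]), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            q_root_new = q_root + delta[:R]
            theta_new = np.clip(theta + delta[R:], ranges[:, 0], ranges[:, 1])
            new_cost = cost_only(q_root_new, theta_new)
            if new_cost < cost:
                accepted = True
                break
            lam *= 10.0
            if lam > 1e10:
                break
        if not accepted:
            break
        step = np.linalg.norm(np.concatenate([q_root_new - q_root, theta_new - theta]))
        improvement = cost - new_cost
        q_root, theta, cost = q_root_new, theta_new, new_cost
        trace.append(cost)
        lam = max(lam / 3.0, 1e-12)
        cost, r, J, deriv = residual_and_jac(q_root, theta)
        if step < config.step_tol or improvement < config.cost_tol * max(cost, 1e-12):
            converged = True
            break
    rms = _segment_rms(topo, deriv.marker_positions, observed, present)
    root_R = root_transform_from_angles(model.root_joint, q_root)[:3, :3]
    return IKFrameResult(
        theta=theta,
        root_angles=q_root,
        root_rotation=root_R,
        segment_rms=rms,
        objective=cost,
        objective_trace=trace,
        converged=converged,
        n_iter=it,
    )


def _coordinate_body_adjacency(model: SkeletalModel) -> np.ndarray:
    """(C, B) mask: coordinate c is adjacent to body b (its joint's parent or child)."""
    topo = _topology(model)
    adj = np.zeros((topo.n_coords, len(topo.body_names)), dtype=bool)
    for ji in topo.joints:
        for ci in ji.coord_idx:
            adj[ci, ji.parent] = True
            adj[ci, ji.child] = True
    return adj


def solve_ik_sequence(
    model: SkeletalModel,
    scales: BodyScales | None,
    trajectory: MarkerTrajectory,
    config: IKConfig | None = None,
) -> IKResult:
    """Inverse kinematics over a uniformly sampled marker trajectory.

    Frame t is warm-started from frame t-1 (the first frame from the neutral
    pose).  Coordinates adjacent to any segment whose marker RMS residual
    exceeds ``config.reject_mm`` in a frame are flagged invalid for that
    frame.  An empty trajectory yields an empty result.
    """
    config = config or IKConfig()
    topo = _topology(model)
    F = trajectory.n_frames
    C = topo.n_coords
    B = len(topo.body_names)
    R = len(model.root_joint.dofs) if model.root_joint else 0
    coord_names = list(topo.coordinate_names)
    if F == 0:
        return IKResult(
            motion=MotionSequence(coord_names, np.empty(0), np.empty((0, C)), np.empty((0, 3, 3))),
            root_angles=np.empty((0, R)),
            segment_rms=np.empty((0, B)),
            objective=np.empty(0),
            converged=np.empty(0, dtype=bool),
        )
    if list(trajectory.marker_names) != list(model.marker_names):
        raise ValueError("trajectory markers must match the model's markers (same order)")
    angles = np.empty((F, C))
    roots = np.empty((F, 3, 3))
    root_angles = np.empty((F, R))
    seg_rms = np.empty((F, B))
    objective = np.empty(F)
    converged = np.empty(F, dtype=bool)
    theta0, q0 = None, None
    for f in range(F):
        res = solve_ik_frame(
            model,
            scales,
            trajectory.positions[f],
            missing=trajectory.missing[f],
            theta_init=theta0,
            root_angles_init=q0,
            config=config,
        )
        angles[f] = res.theta
        roots[f] = res.root_rotation
        root_angles[f] = res.root_angles
        seg_rms[f] = res.segment_rms
        objective[f] = res.objective
        converged[f] = res.converged
        theta0, q0 = res.theta, res.root_angles
    if config.smooth_cutoff_hz is not None and F > 12:
        rate = 1.0 / trajectory.dt
        angles = lowpass_smooth(angles, config.smooth_cutoff_hz, rate)
    adjacency = _coordinate_body_adjacency(model)
    threshold = config.reject_mm * 1e-3
    over = np.nan_to_num(seg_rms, nan=0.0) > threshold  # (F, B)
    valid = ~(over @ adjacency.T).astype(bool)  # (F, C)
    motion = MotionSequence(coord_names, trajectory.timestamps.copy(), angles, roots, valid)
    return IKResult(
        motion=motion,
        root_angles=root_angles,
        segment_rms=seg_rms,
        objective=objective,
        converged=converged,
    )


def lowpass_smooth(series, cutoff_hz: float, rate_hz: float) -> np.ndarray:
    """Zero-phase (forward-backward) 4th-order Butterworth low-pass filter.

    Constant signals pass through unchanged; ``cutoff_hz`` must be below the
    Nyquist frequency ``rate_hz / 2``.
    """
    s = np.asarray(series, dtype=float)
    if cutoff_hz <= 0 or cutoff_hz >= rate_hz / 2:
        raise ValueError("cutoff must satisfy 0 < cutoff < rate / 2")
    b, a = signal.butter(4, cutoff_hz / (rate_hz / 2))
    padlen = min(3 * max(len(a), len(b)), s.shape[0] - 1)
    return signal.filtfilt(b, a, s, axis=0, padlen=padlen)
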