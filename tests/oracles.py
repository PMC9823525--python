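"""Independent oracle implementations used to cross-check the package.

Everything here is written from scratch against the defining equations —
literal transcriptions using plain numpy / scipy only — and deliberately does
not reuse any of the package's kinematics internals.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def rodrigues(axis, angle):
    """Rodrigues rotation formula, term by term."""
    a = np.asarray(axis, dtype=float)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def euler_xyz(o):
    """Intrinsic body-fixed X-Y-Z Euler angles via scipy (independent route)."""
    return Rotation.from_euler("XYZ", o).as_matrix()


def motion_matrix(axes, thetas):
    """Literal sequence: R1 = G(A1,t1); R2 = G(R1 A2,t2); R3 = G(R2 R1 A3,t3);
    rotation = R3 R2 R1 embedded in a 4x4 with zero translation."""
    Rs = []
    acc = np.eye(3)
    for A, t in zip(axes, thetas):
        R = rodrigues(acc @ np.asarray(A, float), t)
        Rs.append(R)
        acc = R @ acc
    out = np.eye(4)
    # explicit product R3 @ R2 @ R1 (identity for absent dofs)
    M = np.eye(3)
    for R in Rs:
        M = R @ M
    out[:3, :3] = M
    return out


def frame_matrix(euler, translation):
    out = np.eye(4)
    out[:3, :3] = euler_xyz(euler)
    out[:3, 3] = np.asarray(translation, float)
    return out


def parent_child_matrix(joint, thetas, parent_ratio, child_ratio):
    """R_parent<-joint @ R_motion @ R_child<-joint^-1 with scaled translations,
    inverted with a general matrix inverse."""
    tp = np.asarray(joint.translation_in_parent, float) * np.asarray(parent_ratio, float)
    tc = np.asarray(joint.translation_in_child, float) * np.asarray(child_ratio, float)
    A_p = frame_matrix(joint.orientation_in_parent, tp)
    A_c = frame_matrix(joint.orientation_in_child, tc)
    axes = [d.axis for d in joint.dofs]
    return A_p @ motion_matrix(axes, thetas) @ np.linalg.inv(A_c)


def root_matrix(root_joint, thetas):
    """I @ R_motion @ R_pelvis<-joint^-1 with the translation part zeroed."""
    A_c = frame_matrix(root_joint.orientation_in_child, root_joint.translation_in_child)
    axes = [d.axis for d in root_joint.dofs]
    out = np.eye(4) @ motion_matrix(axes, thetas) @ np.linalg.inv(A_c)
    out[:3, 3] = 0.0
    return out


def path_product_fk(model, scale_values, theta_map, root_4x4):
    """Forward kinematics by per-marker path products.

    For every marker, multiplies the parent-from-child transforms along the
    path from the root body to the marker's anchor (prepending the supplied
    root transform) and applies the scaled marker offset — no level-order
    traversal, no shared state between markers.
    """
    bidx = {b.name: i for i, b in enumerate(model.bodies)}
    joint_to_child = {j.child_body: j for j in model.joints}
    out = np.zeros((len(model.markers), 3))
    joints_out = {}
    for mi, marker in enumerate(model.markers):
        path = []
        body = marker.anchor_body
        while body != model.root_body:
            j = joint_to_child[body]
            path.append(j)
            body = j.parent_body
        T = np.array(root_4x4, dtype=float)
        for j in reversed(path):
            thetas = [theta_map[d.coordinate_name] for d in j.dofs]
            T = T @ parent_child_matrix(
                j, thetas, scale_values[bidx[j.parent_body]], scale_values[bidx[j.child_body]]
            )
        d_hat = np.asarray(marker.offset, float) * scale_values[bidx[marker.anchor_body]]
        out[mi] = (T @ np.append(d_hat, 1.0))[:3]
    for j in model.joints:
        path = []
        body = j.child_body
        while body != model.root_body:
            jj = joint_to_child[body]
            path.append(jj)
            body = jj.parent_body
        T = np.array(root_4x4, dtype=float)
        for jj in reversed(path):
            thetas = [theta_map[d.coordinate_name] for d in jj.dofs]
            T = T @ parent_child_matrix(
                jj, thetas, scale_values[bidx[jj.parent_body]], scale_values[bidx[jj.child_body]]
            )
        joints_out[j.name] = T[:3, 3]
    return out, joints_out
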