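"""Training losses and evaluation metrics for kinematic estimation.

The composite training loss weights four terms — root-relative L1 losses on
joint and marker positions plus plain L1 losses on body scales and joint
angles.  Evaluation metrics cover the mean per-bony-landmark position error
(MPBLPE), joint-angle error statistics, body-scale errors in both unitless
and millimeter form, mean velocities as a smoothness measure, and Pearson
correlations with the conventional strength categories.

Positions are meters and angles radians on the way in; reports use
millimeters and degrees, matching how results in this field are printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LossConfig",
    "MetricReport",
    "root_relative_l1",
    "composite_loss",
    "mpblpe",
    "body_scale_errors",
    "angle_errors",
    "mean_velocity",
    "pearson_with_category",
    "summarize_distribution",
]


@dataclass
class LossConfig:
    """Non-negative weights of the composite loss.

    Defaults are the weights used for supervising the skeletal-model layer:
    joint positions 1.0, marker positions 2.0, body scales 0.1, joint angles
    0.06.
    """

    lambda_joint: float = 1.0
    lambda_marker: float = 2.0
    lambda_body: float = 0.1
    lambda_angle: float = 0.06

    def __post_init__(self) -> None:
        for name in ("lambda_joint", "lambda_marker", "lambda_body", "lambda_angle"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")


def root_relative_l1(pred, truth, root_index: int = 0) -> float:
    """Sum of |(pred - pred_root) - (truth - truth_root)| over points and axes.

    Subtracting each set's own root position first cancels any global
    translation, so the loss measures pose shape only.
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    p = p - p[..., root_index : root_index + 1, :]
    t = t - t[..., root_index : root_index + 1, :]
    return float(np.sum(np.abs(p - t)))


def composite_loss(
    pred: dict,
    truth: dict,
    cfg: LossConfig | None = None,
    root_joint_index: int = 0,
    root_marker_index: int = 0,
) -> tuple[float, dict]:
    """Weighted sum of the four supervision terms, with a per-term breakdown.

    ``pred`` and ``truth`` are mappings with keys ``joint_positions``,
    ``marker_positions``, ``body_scales`` and ``joint_angles``.  Joint and
    marker terms are root-relative L1; scale and angle terms are plain L1
    sums.
    """
    cfg = cfg or LossConfig()
    terms = {
        "joint": root_relative_l1(
            pred["joint_positions"], truth["joint_positions"], root_joint_index
        ),
        "marker": root_relative_l1(
            pred["marker_positions"], truth["marker_positions"], root_marker_index
        ),
        "body": float(
            np.sum(np.abs(np.asarray(pred["body_scales"], float) - np.asarray(truth["body_scales"], float)))
        ),
        "angle": float(
            np.sum(np.abs(np.asarray(pred["joint_angles"], float) - np.asarray(truth["joint_angles"], float)))
        ),
    }
    total = (
        cfg.lambda_joint * terms["joint"]
        + cfg.lambda_marker * terms["marker"]
        + cfg.lambda_body * terms["body"]
        + cfg.lambda_angle * terms["angle"]
    )
    return float(total), terms


def _root_positions(markers: np.ndarray, root) -> np.ndarray:
    """Resolve a per-frame (F, 3) root position from an index or explicit array."""
    if isinstance(root, (int, np.integer)):
        return markers[:, int(root), :]
    arr = np.asarray(root, dtype=float)
    if arr.shape != (markers.shape[0], 3):
        raise ValueError("root positions must be (F, 3) or a marker index")
    return arr


def mpblpe(pred, truth, bony_mask, pred_root=0, truth_root=0) -> float:
    """Mean per-bony-landmark position error in mm.

    Each frame of prediction and ground truth is first aligned at its root
    position; the result is the pooled mean Euclidean distance over frames
    and bony landmarks.
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.ndim != 3:
        raise ValueError("expected matching (F, M, 3) marker arrays")
    bony = np.asarray(bony_mask, dtype=bool)
    if not bony.any():
        raise ValueError("bony-landmark subset is empty")
    p = p - _root_positions(p, pred_root)[:, None, :]
    t = t - _root_positions(t, truth_root)[:, None, :]
    dist = np.linalg.norm(p[:, bony] - t[:, bony], axis=-1)
    return float(np.mean(dist) * 1e3)


def body_scale_errors(
    pred_scales,
    true_scales,
    reference_lengths,
    long_axes=None,
) -> tuple[float, float]:
    """(RMSE_body, MAE_body-in-mm) of predicted body-scale factors.

    RMSE pools every scale entry (all bodies, all axes, all frames).  For the
    mm form, the scale error along each body's longest dimension is converted
    with that body's default reference length (mm) and averaged.
    ``pred_scales`` may be (B, 3) or per-frame (F, B, 3).
    """
    p = np.asarray(pred_scales, dtype=float)
    t = np.asarray(true_scales, dtype=float)
    if p.ndim == 2:
        p = p[None]
    if t.ndim == 2:
        t = np.broadcast_to(t, p.shape)
    if p.shape != t.shape:
        raise ValueError(f"scale shape mismatch {p.shape} vs {t.shape}")
    ref = np.asarray(reference_lengths, dtype=float)
    B = p.shape[1]
    axes = np.ones(B, dtype=int) if long_axes is None else np.asarray(long_axes, dtype=int)
    rmse = float(np.sqrt(np.mean((p - t) ** 2)))
    idx = np.arange(B)
    err_long = np.abs(p[:, idx, axes] - t[:, idx, axes])  # (F, B)
    mae_mm = float(np.mean(err_long * ref))
    return rmse, mae_mm


@dataclass
class AngleErrorStats:
    """Joint-angle error statistics in degrees (population SD convention)."""

    mae: float
    sd: float
    rmse: float
    per_coordinate_mae: np.ndarray
    per_coordinate_sd: np.ndarray
    per_coordinate_rmse: np.ndarray


def angle_errors(pred, truth, valid=None) -> AngleErrorStats:
    """MAE, SD and RMSE of joint-angle errors, in degrees.

    Inputs are radians, (F, C); entries where ``valid`` is false are ignored.
    SD is the population standard deviation of the signed errors.
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.ndim != 2:
        raise ValueError("expected matching (F, C) angle arrays")
    mask = np.ones(p.shape, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    err = np.rad2deg(p - t)
    C = p.shape[1]
    pc_mae = np.full(C, np.nan)
    pc_sd = np.full(C, np.nan)
    pc_rmse = np.full(C, np.nan)
    for c in range(C):
        e = err[mask[:, c], c]
        if len(e):
            pc_mae[c] = np.mean(np.abs(e))
            pc_sd[c] = np.std(e)
            pc_rmse[c] = np.sqrt(np.mean(e**2))
    pooled = err[mask]
    if len(pooled) == 0:
        raise ValueError("no valid entries to evaluate")
    return AngleErrorStats(
        mae=float(np.mean(np.abs(pooled))),
        sd=float(np.std(pooled)),
        rmse=float(np.sqrt(np.mean(pooled**2))),
        per_coordinate_mae=pc_mae,
        per_coordinate_sd=pc_sd,
        per_coordinate_rmse=pc_rmse,
    )


def mean_velocity(series, dt: float) -> np.ndarray:
    """Mean absolute first difference per unit time, per channel.

    ``MV = sum_t |s_t - s_{t+1}| / dt / n`` with n the number of consecutive
    pairs (#frames - 1); exact |slope| for affine signals.  ``series`` is
    (F,) or (F, C); returns a scalar array per channel.
    """
    s = np.asarray(series, dtype=float)
    if s.shape[0] < 2:
        raise ValueError("need at least two samples")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return np.sum(np.abs(np.diff(s, axis=0)), axis=0) / dt / (s.shape[0] - 1)


#: Category cut points on |rho|: weak <= 0.35 < moderate <= 0.67 < strong <= 0.90 < excellent.
RHO_CATEGORIES = ((0.35, "weak"), (0.67, "moderate"), (0.90, "strong"))


def pearson_with_category(a, b) -> tuple[float, str]:
    """Pearson correlation with the conventional strength category on |rho|.

    Boundaries are inclusive on the lower category (|rho| = 0.35 is "weak").
    Constant input makes the correlation undefined and raises ``ValueError``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1-D series of >= 3 samples")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a constant series")
    rho = float(stats.pearsonr(a, b).statistic)
    mag = abs(rho)
    for cut, label in RHO_CATEGORIES:
        if mag <= cut:
            return rho, label
    return rho, "excellent"


def summarize_distribution(values) -> dict:
    """Median, IQR (linear-interpolation quantiles), mean and population SD."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q1, q3 = np.percentile(v, [25, 75])
    return {
        "median": float(np.median(v)),
        "iqr": float(q3 - q1),
        "mean": float(np.mean(v)),
        "sd": float(np.std(v)),
    }


@dataclass
class MetricReport:
    """Every evaluation metric for one estimated sequence set.

    Position errors in mm, angle errors in degrees, velocities in mm/s and
    deg/s; ``rho`` maps coordinate names to (correlation, category) pairs.
    """

    mpblpe: float
    mae_angle: float
    sd_angle: float
    rmse_angle: float
    rmse_body: float
    mae_body: float
    mv_bl: float
    mv_angle: float
    per_coordinate_mae: dict = field(default_factory=dict)
    rho: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mpblpe_mm": self.mpblpe,
            "mae_angle_deg": self.mae_angle,
            "sd_angle_deg": self.sd_angle,
            "rmse_angle_deg": self.rmse_angle,
            "rmse_body": self.rmse_body,
            "mae_body_mm": self.mae_body,
            "mv_bl_mm_per_s": self.mv_bl,
            "mv_angle_deg_per_s": self.mv_angle,
            "per_coordinate_mae_deg": dict(self.per_coordinate_mae),
            "rho": {k: list(v) for k, v in self.rho.items()},
        }
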