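"""Rigid head-motion estimation and the scalar motion index.

Each diffusion-weighted frame is rigidly registered to the b=0 reference by
minimizing the mean squared intensity difference (same subject, same
modality, so plain MSE suffices).  Six parameters are estimated per frame:
three translations in millimetres and three small-angle Euler rotations in
radians about the volume center, applied in x, y, z order.

The per-subject motion index is the sum over the six parameters of the mean
absolute difference between adjacent frames.  Millimetres and radians are
summed, so the index is unitless by construction; it is invariant to a
static offset of any parameter series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .io import DWIVolume, GradientTable, log

__all__ = [
    "MotionTrace",
    "rigid_matrix",
    "transform_volume",
    "register_rigid",
    "estimate_motion",
    "motion_index",
]

# Powell works on scaled variables so a unit step means roughly one voxel of
# translation or ~3 degrees of rotation.
_PARAM_SCALE = np.array([1.0, 1.0, 1.0, 0.05, 0.05, 0.05])
_SMOOTH_SIGMA = 0.8  # voxels, pre-registration smoothing


@dataclass
class MotionTrace:
    """Per-frame rigid parameters (tx, ty, tz mm, rx, ry, rz rad), acquisition order."""

    params: np.ndarray  # (n_frames, 6)
    residuals: np.ndarray | None = None
    converged: np.ndarray | None = None

    def __post_init__(self):
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.shape[1] != 6:
            raise ValueError("motion trace rows must have 6 parameters")

    def __len__(self) -> int:
        return len(self.params)


def _euler(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def rigid_matrix(params, shape, voxel_dims) -> np.ndarray:
    """Homogeneous voxel-space matrix for a rigid motion about the volume center.

    ``params`` = (tx, ty, tz) in mm and (rx, ry, rz) in radians.  The returned
    matrix maps a voxel coordinate p to its moved location R(p-c)+c+t.
    """
    t_mm = np.asarray(params[:3], dtype=float)
    R = _euler(*params[3:6])
    c = np.asarray(shape, dtype=float) / 2.0
    t_vox = t_mm / np.asarray(voxel_dims, dtype=float)
    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = c - R @ c + t_vox
    return M


def transform_volume(vol3d: np.ndarray, params, voxel_dims) -> np.ndarray:
    """Apply a rigid motion to a 3D volume (trilinear resampling)."""
    M = rigid_matrix(params, vol3d.shape, voxel_dims)
    inv = np.linalg.inv(M)
    return ndimage.affine_transform(
        vol3d, inv[:3, :3], offset=inv[:3, 3], order=1, mode="nearest"
    )


def register_rigid(moving: np.ndarray, fixed: np.ndarray, voxel_dims,
                   maxiter: int = 3) -> tuple:
    """Estimate the 6 rigid parameters aligning ``moving`` onto ``fixed``.

    Minimizes mean squared intensity difference with Powell's derivative-free
    method from a zero initialization.  Returns (params, residual, converged).
    """
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed volumes must share a grid")
    # Light smoothing suppresses noise and gradient-specific texture; both
    # images are z-scored so the cost is the MSE of standardized intensities
    # (equivalently normalized cross-correlation) — the diffusion-weighted
    # frames are globally darker than the b=0 target and carry a different
    # tissue contrast, which raw MSE would mistake for misalignment.
    fixed = ndimage.gaussian_filter(np.asarray(fixed, dtype=float), _SMOOTH_SIGMA)
    moving = ndimage.gaussian_filter(np.asarray(moving, dtype=float), _SMOOTH_SIGMA)

    def zscore(a):
        sd = a.std()
        return (a - a.mean()) / (sd if sd > 0 else 1.0)

    fixed = zscore(fixed)

    def cost(z):
        aligned = transform_volume(moving, z * _PARAM_SCALE, voxel_dims)
        d = zscore(aligned) - fixed
        return float(np.mean(d * d))

    res = optimize.minimize(
        cost, np.zeros(6), method="Powell",
        options={"xtol": 5e-3, "ftol": 1e-4, "maxiter": maxiter},
    )
    params = res.x * _PARAM_SCALE
    if not res.success and not np.isfinite(res.fun):
        log("rigid registration failed to converge; returning zero parameters")
        return np.zeros(6), float("nan"), False
    return params, float(res.fun), bool(res.success)


def estimate_motion(volume: DWIVolume, table: GradientTable) -> MotionTrace:
    """Register every b>0 frame to the first b=0 frame."""
    b0_idx = int(np.flatnonzero(table.b0_mask)[0])
    fixed = volume.frame(b0_idx)
    rows, resids, conv = [], [], []
    for i in np.flatnonzero(table.dwi_mask):
        p, r, ok = register_rigid(volume.frame(int(i)), fixed, volume.voxel_dims)
        rows.append(p)
        resids.append(r)
        conv.append(ok)
    return MotionTrace(np.array(rows), np.array(resids), np.array(conv))


def motion_index(trace: MotionTrace) -> float:
    """Unitless head-motion index: summed mean absolute adjacent-frame displacement."""
    p = trace.params
    if len(p) < 2:
        log("motion index requested for a single frame; returning 0")
        return 0.0
    return float(np.sum(np.mean(np.abs(np.diff(p, axis=0)), axis=0)))
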