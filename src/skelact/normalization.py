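"""Pose normalization: remove translation and heading (y-axis rotation).

Each pose is shifted so the root joint sits at the origin, then rotated
about the vertical y-axis so the hip-to-hip vector lies along +z, which
orients the subject's facing direction toward +x.  Only the heading is
removed — tilt/lean is part of how the motion is performed and is kept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .types import Motion

__all__ = [
    "DegenerateHipsError",
    "NormalizationConfig",
    "center_pose",
    "heading_angle",
    "rotate_about_y",
    "normalize_pose",
    "normalize_motion",
]

logger = logging.getLogger(__name__)

#: xz-projection lengths below this are treated as "no heading".
DEGENERATE_HIP_EPS = 1e-12


class DegenerateHipsError(ValueError):
    """The hip-to-hip vector has no usable xz-projection (no heading)."""


@dataclass(frozen=True)
class NormalizationConfig:
    """Joint indices used for translational and heading normalization.

    ``right_hip_index - left_hip_index`` (as position vectors) is aligned
    to +z; the paper does not fix the left/right order, so both indices are
    explicit configuration.
    """

    root_index: int = 0
    left_hip_index: int = 1
    right_hip_index: int = 2
    per_frame: bool = True

    def validate(self, n_joints: int) -> None:
        idx = (self.root_index, self.left_hip_index, self.right_hip_index)
        if len(set(idx)) != 3:
            raise ValueError(f"root/hip indices must be distinct, got {idx}")
        for i in idx:
            if not 0 <= i < n_joints:
                raise IndexError(f"joint index {i} out of range [0, {n_joints})")


def center_pose(pose: np.ndarray, root_index: int = 0) -> np.ndarray:
    """Translate *pose* so the root joint is exactly at the origin."""
    pose = np.asarray(pose, dtype=np.float64)
    if not 0 <= root_index < pose.shape[0]:
        raise IndexError(
            f"root_index {root_index} out of range [0, {pose.shape[0]})"
        )
    return pose - pose[root_index]


def heading_angle(pose: np.ndarray, cfg: NormalizationConfig) -> float:
    """Angle θ ∈ (−π, π] whose y-rotation puts the hip vector along +z.

    The hip vector is ``pose[right_hip] - pose[left_hip]``.  After rotating
    the pose by θ (see :func:`rotate_about_y`) its x-component is 0 and its
    z-component is ≥ 0.

    Raises
    ------
    DegenerateHipsError
        If the hip vector's xz-projection is shorter than 1e-12; the caller
        should treat the rotation as identity.
    """
    pose = np.asarray(pose, dtype=np.float64)
    v = pose[cfg.right_hip_index] - pose[cfg.left_hip_index]
    vx, vz = float(v[0]), float(v[2])
    if math.hypot(vx, vz) < DEGENERATE_HIP_EPS:
        raise DegenerateHipsError(
            "hip vector has near-zero xz-projection; no heading defined"
        )
    theta = math.atan2(-vx, vz)
    if theta <= -math.pi:  # map the branch point so θ ∈ (−π, π]
        theta = math.pi
    return theta


def rotate_about_y(pose: np.ndarray, angle: float) -> np.ndarray:
    """Rotate every joint about the y-axis: (x,y,z) → (x·c + z·s, y, −x·s + z·c)."""
    pose = np.asarray(pose, dtype=np.float64)
    if not math.isfinite(angle):
        raise ValueError(f"angle must be finite, got {angle}")
    c, s = math.cos(angle), math.sin(angle)
    out = np.empty_like(pose)
    out[:, 0] = pose[:, 0] * c + pose[:, 2] * s
    out[:, 1] = pose[:, 1]
    out[:, 2] = -pose[:, 0] * s + pose[:, 2] * c
    return out


def normalize_pose(
    pose: np.ndarray, cfg: NormalizationConfig = NormalizationConfig()
) -> np.ndarray:
    """Root-center then remove heading; degenerate hips skip the rotation."""
    pose = np.asarray(pose, dtype=np.float64)
    cfg.validate(pose.shape[0])
    centered = center_pose(pose, cfg.root_index)
    try:
        theta = heading_angle(centered, cfg)
    except DegenerateHipsError:
        logger.warning("degenerate hip projection; skipping heading removal")
        return centered
    return rotate_about_y(centered, theta)


def normalize_motion(
    motion: Motion, cfg: NormalizationConfig = NormalizationConfig()
) -> Motion:
    """Normalize every frame of *motion*.

    With ``cfg.per_frame`` true each frame is normalized independently;
    otherwise every frame is root-centered and a single rotation, computed
    from the first frame's heading, is applied to all frames.
    """
    cfg.validate(motion.n_joints)
    if cfg.per_frame:
        frames = np.stack([normalize_pose(f, cfg) for f in motion.frames])
    else:
        centered = [center_pose(f, cfg.root_index) for f in motion.frames]
        try:
            theta = heading_angle(centered[0], cfg)
        except DegenerateHipsError:
            logger.warning(
                "degenerate hips in first frame; skipping heading removal"
            )
            theta = 0.0
        frames = np.stack([rotate_about_y(f, theta) for f in centered])
    return Motion(
        frames=frames,
        fps=motion.fps,
        motion_id=motion.motion_id,
        label=motion.label,
    )
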