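"""Synthetic labeled skeleton motions for testing the full pipeline.

Each class is a fixed sinusoidal displacement pattern (class-specific
frequency, per-joint direction and phase) applied to a deterministic
skeleton template.  On top of the class signal each motion gets the exact
nuisance the normalization step removes — a constant random heading
rotation about y and a linear root translation drift — plus white Gaussian
joint noise.  The root and hip joints carry no class displacement, so with
the nuisance and noise switched off a generated motion is already
normalized and equals its class archetype exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .normalization import rotate_about_y
from .types import Motion, MotionDataset

__all__ = [
    "SyntheticConfig",
    "make_skeleton_template",
    "class_pattern",
    "generate_motion",
    "generate_dataset",
]

# Entropy prefix making class patterns independent of motion-level seeds.
_CLASS_PATTERN_KEY = 0x5AE1C0DE

#: Joint indices carrying no class displacement (root + hip pair).
FIXED_JOINTS = (0, 1, 2)
HIP_HALF_WIDTH = 10.0  # cm


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults sized for stable end-to-end runs."""

    n_classes: int = 5
    motions_per_class: int = 30
    n_joints: int = 31
    frame_range: tuple[int, int] = (40, 200)
    fps: float = 120.0
    noise_sigma: float = 0.5
    heading_range: float = 2.0 * np.pi
    drift_speed: float = 1.0
    amplitude_range: tuple[float, float] = (5.0, 25.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.motions_per_class < 1:
            raise ValueError("counts must be positive")
        if self.n_joints < 3:
            raise ValueError("need at least 3 joints (root + hip pair)")
        if self.frame_range[0] < 2 or self.frame_range[1] < self.frame_range[0]:
            raise ValueError("frame_range must be [lo, hi] with lo >= 2")
        if self.noise_sigma < 0 or self.heading_range < 0:
            raise ValueError("noise_sigma and heading_range must be >= 0")


def make_skeleton_template(n_joints: int = 31) -> tuple[np.ndarray, tuple[int, int]]:
    """Deterministic toy body; returns (pose, (left_hip, right_hip)).

    Root (joint 0) at the origin, left/right hips at -z/+z, remaining
    joints on fixed limb-like offsets.  The template is already normalized.
    """
    if n_joints < 3:
        raise ValueError("need at least 3 joints")
    pose = np.zeros((n_joints, 3))
    pose[1] = (0.0, 0.0, -HIP_HALF_WIDTH)
    pose[2] = (0.0, 0.0, +HIP_HALF_WIDTH)
    # spine/limb-ish layout: alternate sides, rise with index, reach along x
    for j in range(3, n_joints):
        side = -1.0 if j % 2 else 1.0
        tier = (j - 3) // 4
        pose[j] = (
            5.0 + 3.0 * ((j - 3) % 4),
            12.0 * tier - 20.0,
            side * (4.0 + 2.0 * (j % 3)),
        )
    return pose, (1, 2)


def class_pattern(
    class_id: int, n_joints: int
) -> tuple[float, np.ndarray, np.ndarray]:
    """Fixed per-class signal: (frequency_hz, directions (J,3), phases (J,)).

    Frequency is ``0.5 + 0.3 * class_id`` Hz; directions are unit vectors
    and phases uniform in [0, 2π), both drawn from a class-keyed generator
    so they depend on nothing but the class.  Root and hips get zero
    displacement.
    """
    rng = np.random.default_rng([_CLASS_PATTERN_KEY, class_id])
    directions = rng.normal(size=(n_joints, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_joints)
    for j in FIXED_JOINTS:
        directions[j] = 0.0
        phases[j] = 0.0
    return 0.5 + 0.3 * class_id, directions, phases


def archetype_frames(
    class_id: int, cfg: SyntheticConfig, n_frames: int, amplitude: float
) -> np.ndarray:
    """Noise- and nuisance-free frames of one class at a given amplitude."""
    template, _ = make_skeleton_template(cfg.n_joints)
    freq, directions, phases = class_pattern(class_id, cfg.n_joints)
    t = np.arange(n_frames) / cfg.fps
    wave = np.sin(2.0 * np.pi * freq * t[:, None] + phases[None, :])
    return template[None] + amplitude * wave[:, :, None] * directions[None]


def generate_motion(
    class_id: int, cfg: SyntheticConfig, seed
) -> Motion:
    """One labeled motion: class archetype + heading/drift nuisance + noise."""
    if not 0 <= class_id < cfg.n_classes:
        raise ValueError(f"class_id {class_id} out of range [0, {cfg.n_classes})")
    rng = np.random.default_rng(seed)
    n = int(rng.integers(cfg.frame_range[0], cfg.frame_range[1] + 1))
    amplitude = float(rng.uniform(*cfg.amplitude_range))
    heading = float(rng.uniform(-0.5, 0.5) * cfg.heading_range)
    drift_dir = rng.normal(size=3)
    norm = np.linalg.norm(drift_dir)
    drift_dir = drift_dir / norm if norm > 0 else np.zeros(3)

    frames = archetype_frames(class_id, cfg, n, amplitude)
    frames = np.stack([rotate_about_y(f, heading) for f in frames])
    drift = cfg.drift_speed * np.arange(n)[:, None] * drift_dir[None]
    frames += drift[:, None, :]
    if cfg.noise_sigma > 0:
        frames += rng.normal(0.0, cfg.noise_sigma, size=frames.shape)
    return Motion(
        frames=frames,
        fps=cfg.fps,
        label=f"class{class_id:02d}",
    )


def generate_dataset(cfg: SyntheticConfig) -> MotionDataset:
    """``n_classes × motions_per_class`` labeled motions, fully seeded."""
    motions = []
    for c in range(cfg.n_classes):
        for m in range(cfg.motions_per_class):
            motion = generate_motion(c, cfg, seed=[cfg.seed, c, m])
            motion.motion_id = f"class{c:02d}_m{m:03d}"
            motions.append(motion)
    return MotionDataset(
        motions=motions,
        classes=tuple(f"class{c:02d}" for c in range(cfg.n_classes)),
    )
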