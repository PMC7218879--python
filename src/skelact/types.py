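"""Core domain types: poses, motions and labeled motion datasets.

A *pose* is a single frame of J joints in 3D, stored as a float ndarray of
shape ``(J, 3)`` in dataset-native units (centimeters by default), y-up.
A :class:`Motion` is an ordered sequence of poses sharing the same joint
count, with a frame rate and an optional class label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Motion",
    "MotionDataset",
    "as_pose",
    "validate_pose",
]

DEFAULT_FPS = 120.0


def as_pose(joints) -> np.ndarray:
    """Coerce *joints* to a ``(J, 3)`` float64 pose array.

    Raises ``ValueError`` if the shape is not ``(J, 3)`` with ``J >= 2``.
    """
    pose = np.asarray(joints, dtype=np.float64)
    if pose.ndim != 2 or pose.shape[1] != 3:
        raise ValueError(f"pose must have shape (J, 3), got {pose.shape}")
    if pose.shape[0] < 2:
        raise ValueError(f"pose needs at least 2 joints, got {pose.shape[0]}")
    return pose


def validate_pose(pose: np.ndarray) -> None:
    """Raise ``ValueError`` if any coordinate is non-finite."""
    if not np.isfinite(pose).all():
        bad = np.argwhere(~np.isfinite(pose))
        j, c = bad[0]
        raise ValueError(f"non-finite coordinate at joint {j}, axis {c}")


@dataclass
class Motion:
    """An ordered pose sequence with frame rate, identifier and optional label.

    Parameters
    ----------
    frames
        Array of shape ``(n, J, 3)``; ``n >= 1``, ``J >= 2``.
    fps
        Frames per second, ``> 0``.
    motion_id
        Free-form identifier.
    label
        Optional class-name string.
    """

    frames: np.ndarray
    fps: float = DEFAULT_FPS
    motion_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(
                f"frames must have shape (n, J, 3), got {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("a motion needs at least one frame")
        if self.frames.shape[1] < 2:
            raise ValueError("poses need at least 2 joints")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_joints(self) -> int:
        return self.frames.shape[1]

    def validate_finite(self) -> None:
        """Raise ``ValueError`` naming the first non-finite coordinate."""
        if not np.isfinite(self.frames).all():
            bad = np.argwhere(~np.isfinite(self.frames))
            f, j, c = bad[0]
            raise ValueError(
                f"non-finite coordinate at frame {f}, joint {j}, axis {c}"
            )

    def copy(self) -> "Motion":
        return Motion(
            frames=self.frames.copy(),
            fps=self.fps,
            motion_id=self.motion_id,
            label=self.label,
        )


@dataclass
class MotionDataset:
    """Labeled motions plus an ordered (lexicographic) class vocabulary."""

    motions: list[Motion] = field(default_factory=list)
    classes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class names")
        for m in self.motions:
            if m.label is None:
                raise ValueError(f"motion {m.motion_id!r} has no label")
            if m.label not in self.classes:
                raise ValueError(
                    f"motion {m.motion_id!r} labeled {m.label!r}, "
                    f"not in classes {self.classes}"
                )

    @classmethod
    def from_motions(cls, motions: list[Motion]) -> "MotionDataset":
        """Build a dataset with classes inferred as sorted unique labels."""
        labels = sorted({m.label for m in motions if m.label is not None})
        return cls(motions=list(motions), classes=tuple(labels))

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def class_index(self, label: str) -> int:
        return self.classes.index(label)

    def __len__(self) -> int:
        return len(self.motions)
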