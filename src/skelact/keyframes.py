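"""Keyframe extraction by iterative nearest-neighbor candidate filtering.

Starting from the full motion, each iteration takes the earliest remaining
frame as query, gathers its nearest neighbors among the *other* remaining
frames (by average per-joint Euclidean distance), keeps the query plus
those strictly closer than the threshold as the candidate set, and selects
the candidate set's median frame (by temporal order) as a keyframe.  The whole candidate set is then
discarded, so iterations partition the motion and terminate in at most n
steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .types import Motion

__all__ = [
    "NeighborQueryResult",
    "KeyframeExtractionResult",
    "average_pose_distance",
    "find_nearest_neighbors",
    "extract_keyframes",
    "threshold_sweep",
]

KPolicy = Literal["fixed", "half_remaining"]


@dataclass(frozen=True)
class NeighborQueryResult:
    """Nearest-neighbor frame indices with matching distances.

    Sorted by ascending distance, ties broken by ascending frame index.
    """

    neighbor_indices: tuple[int, ...]
    distances: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.neighbor_indices) != len(self.distances):
            raise ValueError("indices and distances must have equal length")
        d = np.asarray(self.distances, dtype=np.float64)
        if d.size:
            if not np.isfinite(d).all() or (d < 0).any():
                raise ValueError("distances must be finite and non-negative")
            if (np.diff(d) < 0).any():
                raise ValueError("distances must be non-decreasing")


@dataclass
class KeyframeExtractionResult:
    """Selected keyframes plus the per-iteration candidate sets.

    ``keyframes`` holds ascending 0-based indices into the original motion;
    ``candidate_sets[i]`` is the set discarded at iteration ``i`` and always
    contains the keyframe selected at that iteration.  The candidate sets
    are pairwise disjoint and their union is exactly ``{0..n-1}``.
    """

    keyframes: list[int]
    candidate_sets: list[list[int]]
    threshold: float
    k_initial: int
    n: int
    motion_id: str = ""

    def __post_init__(self) -> None:
        if not 1 <= len(self.keyframes) <= self.n:
            raise ValueError("keyframe count must be in [1, n]")
        if len(self.keyframes) != len(self.candidate_sets):
            raise ValueError("one keyframe per candidate set required")
        seen: set[int] = set()
        for kf, phi in zip(self.keyframes, self.candidate_sets):
            if kf not in phi:
                raise ValueError(f"keyframe {kf} not in its candidate set")
            phi_set = set(phi)
            if len(phi_set) != len(phi):
                raise ValueError("duplicate index inside a candidate set")
            if seen & phi_set:
                raise ValueError("candidate sets are not disjoint")
            seen |= phi_set
        if seen != set(range(self.n)):
            raise ValueError("candidate sets do not cover {0..n-1}")

    @property
    def compression_ratio(self) -> float:
        """Fraction of frames removed: ``1 - |keyframes| / n``."""
        return 1.0 - len(self.keyframes) / self.n


def average_pose_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Mean over joints of the 3D Euclidean distance between paired joints."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"pose shapes differ: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b, axis=-1).mean())


def find_nearest_neighbors(
    frames: Mapping[int, np.ndarray], query_index: int, k: int
) -> NeighborQueryResult:
    """The ``min(k, |frames|)`` frames closest to the query, query included.

    *frames* maps frame index → pose array.  The query is its own nearest
    neighbor at distance 0.  Ties are broken by ascending frame index.
    """
    if query_index not in frames:
        raise KeyError(f"query index {query_index} not in collection")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    query = frames[query_index]
    ranked = sorted(
        (average_pose_distance(query, pose), idx) for idx, pose in frames.items()
    )
    top = ranked[: min(k, len(ranked))]
    return NeighborQueryResult(
        neighbor_indices=tuple(idx for _, idx in top),
        distances=tuple(d for d, _ in top),
    )


def extract_keyframes(
    motion: Motion,
    threshold: float = 30.0,
    k_policy: KPolicy = "fixed",
) -> KeyframeExtractionResult:
    """Summarize *motion* to keyframes; expects pre-normalized poses.

    ``k_policy="fixed"`` sets k once to ``n // 2`` and clamps it to the
    remaining-frame count each iteration; ``"half_remaining"`` recomputes
    ``k = remaining // 2`` per iteration.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if k_policy not in ("fixed", "half_remaining"):
        raise ValueError(f"unknown k_policy {k_policy!r}")
    frames = motion.frames
    n = motion.n_frames
    k_initial = n // 2

    remaining = np.arange(n)
    keyframes: list[int] = []
    candidate_sets: list[list[int]] = []
    while remaining.size:
        query = int(remaining[0])
        if k_policy == "fixed":
            k = k_initial
        else:
            k = remaining.size // 2
        # the query is pulled out of the pool before the neighbor search
        rest = remaining[1:]
        k_eff = min(k, rest.size)
        dists = np.linalg.norm(frames[rest] - frames[query], axis=2).mean(axis=1)
        order = np.lexsort((rest, dists))  # distance, then frame index
        near = order[:k_eff]
        phi = {query}
        phi.update(int(rest[i]) for i in near if dists[i] < threshold)
        phi_sorted = sorted(phi)
        keyframes.append(phi_sorted[(len(phi_sorted) - 1) // 2])
        candidate_sets.append(phi_sorted)
        remaining = remaining[~np.isin(remaining, phi_sorted)]

    order = np.argsort(keyframes)
    return KeyframeExtractionResult(
        keyframes=[keyframes[i] for i in order],
        candidate_sets=[candidate_sets[i] for i in order],
        threshold=float(threshold),
        k_initial=k_initial,
        n=n,
        motion_id=motion.motion_id,
    )


def threshold_sweep(
    motion: Motion,
    thresholds: Sequence[float],
    k_policy: KPolicy = "fixed",
) -> list[tuple[float, int]]:
    """Keyframe count per threshold; thresholds must be positive ascending."""
    ts = list(thresholds)
    if any(t <= 0 for t in ts):
        raise ValueError("thresholds must be positive")
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError("thresholds must be strictly ascending")
    return [
        (float(t), len(extract_keyframes(motion, t, k_policy).keyframes))
        for t in ts
    ]
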