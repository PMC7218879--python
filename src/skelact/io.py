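"""Reading and writing motions, datasets, keyframe indices and networks.

Motion CSV dialect (UTF-8, LF newlines):

* line 1 — header ``j00_x,j00_y,j00_z,...`` (three columns per joint),
* line 2 — comment ``# fps=<float>``,
* remaining lines — one frame per row, comma-separated decimal floats
  written at repr precision so the round trip is bitwise lossless.

Datasets live in ``<root>/<class_label>/<motion_id>.csv``.  Keyframe
indices and trained networks are stored as deterministic JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .keyframes import KeyframeExtractionResult
from .network import NetworkParameters
from .types import DEFAULT_FPS, Motion, MotionDataset

__all__ = [
    "FormatError",
    "read_motion_csv",
    "write_motion_csv",
    "load_dataset",
    "write_dataset",
    "write_keyframe_index",
    "read_keyframe_index",
    "save_network",
    "load_network",
]


class FormatError(ValueError):
    """A file does not conform to one of the documented dialects."""


def _header(n_joints: int) -> str:
    return ",".join(
        f"j{j:02d}_{axis}" for j in range(n_joints) for axis in "xyz"
    )


def write_motion_csv(motion: Motion, path) -> None:
    """Write *motion* in the CSV dialect; refuses non-finite coordinates."""
    motion.validate_finite()
    lines = [_header(motion.n_joints), f"# fps={motion.fps!r}"]
    for frame in motion.frames:
        lines.append(",".join(repr(float(v)) for v in frame.reshape(-1)))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_motion_csv(path) -> Motion:
    """Parse a motion CSV; raises :class:`FormatError` naming row/column."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.split("\n") if ln != ""]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split(",")
    n_cols = len(header)
    if n_cols % 3 != 0 or n_cols < 6:
        raise FormatError(
            f"{path}: header has {n_cols} columns, not a multiple of 3 (>= 6)"
        )
    if header != _header(n_cols // 3).split(","):
        raise FormatError(f"{path}: malformed header line")
    if len(lines) < 2 or not lines[1].startswith("# fps="):
        raise FormatError(f"{path}: line 2 must be a '# fps=<float>' comment")
    try:
        fps = float(lines[1][len("# fps="):])
    except ValueError as exc:
        raise FormatError(f"{path}: unparsable fps comment") from exc

    rows = []
    for r, line in enumerate(lines[2:], start=3):
        cells = line.split(",")
        if len(cells) != n_cols:
            raise FormatError(
                f"{path}: row {r} has {len(cells)} columns, expected {n_cols}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError:
            for c, cell in enumerate(cells, start=1):
                try:
                    float(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric cell at row {r}, column {c}"
                    ) from None
    if not rows:
        raise FormatError(f"{path}: no data rows")
    frames = np.array(rows, dtype=np.float64).reshape(len(rows), n_cols // 3, 3)
    return Motion(frames=frames, fps=fps, motion_id=path.stem)


def write_dataset(dataset: MotionDataset, root_dir) -> None:
    """Write ``<root>/<label>/<motion_id>.csv`` for every motion."""
    root = Path(root_dir)
    for m in dataset.motions:
        d = root / m.label
        d.mkdir(parents=True, exist_ok=True)
        write_motion_csv(m, d / f"{m.motion_id}.csv")


def load_dataset(root_dir) -> MotionDataset:
    """Load a dataset directory; classes are sorted subdirectory names."""
    root = Path(root_dir)
    if not root.is_dir():
        raise FormatError(f"{root}: not a directory")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    motions: list[Motion] = []
    n_joints: int | None = None
    for d in class_dirs:
        for f in sorted(d.glob("*.csv")):
            try:
                m = read_motion_csv(f)
            except (OSError, FormatError) as exc:
                raise FormatError(f"failed to read {f}: {exc}") from exc
            if n_joints is None:
                n_joints = m.n_joints
            elif m.n_joints != n_joints:
                raise FormatError(
                    f"{f}: has {m.n_joints} joints, expected {n_joints}"
                )
            m.label = d.name
            motions.append(m)
    if not motions:
        raise FormatError(f"{root}: no motions found")
    return MotionDataset(
        motions=motions, classes=tuple(d.name for d in class_dirs)
    )


def write_keyframe_index(result: KeyframeExtractionResult, path) -> None:
    """Persist a keyframe extraction result as deterministic JSON."""
    payload = {
        "motion_id": result.motion_id,
        "n": result.n,
        "threshold": result.threshold,
        "k": result.k_initial,
        "keyframes": result.keyframes,
        "candidate_sets": result.candidate_sets,
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_keyframe_index(path) -> KeyframeExtractionResult:
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    try:
        n = int(payload["n"])
        keyframes = [int(i) for i in payload["keyframes"]]
        candidate_sets = [
            [int(i) for i in phi] for phi in payload["candidate_sets"]
        ]
        result = KeyframeExtractionResult(
            keyframes=keyframes,
            candidate_sets=candidate_sets,
            threshold=float(payload["threshold"]),
            k_initial=int(payload["k"]),
            n=n,
            motion_id=str(payload["motion_id"]),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing key {exc}") from exc
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for phi in candidate_sets:
        for i in phi:
            if not 0 <= i < n:
                raise FormatError(
                    f"{path}: frame index {i} out of range [0, {n})"
                )
    return result


def save_network(params: NetworkParameters, path, seed: int | None = None) -> None:
    """Store a trained network as deterministic JSON (weights at repr precision)."""
    payload = {
        "format": "skelact-network-v1",
        "layer_sizes": [
            params.input_dim,
            params.w.shape[1],
            params.w_prime.shape[1],
            params.output_dim,
        ],
        "class_names": list(params.class_names),
        "seed": seed,
        "w": params.w.tolist(),
        "w_prime": params.w_prime.tolist(),
        "w_dprime": params.w_dprime.tolist(),
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def load_network(path) -> NetworkParameters:
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    if payload.get("format") != "skelact-network-v1":
        raise FormatError(f"{path}: not a skelact network file")
    try:
        return NetworkParameters(
            w=np.array(payload["w"], dtype=np.float64),
            w_prime=np.array(payload["w_prime"], dtype=np.float64),
            w_dprime=np.array(payload["w_dprime"], dtype=np.float64),
            class_names=tuple(payload["class_names"]),
        )
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
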