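"""End-to-end recognition: features, per-frame voting, cross-validation.

A trained network scores each (key)frame of a test motion; every scored
frame votes for its argmax class and the majority vote decides the action.
The cross-validation harness runs the full train/test protocol with
stratified folds.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np

from .keyframes import KPolicy, extract_keyframes
from .network import NetworkConfig, NetworkParameters, _batch_forward, train
from .normalization import NormalizationConfig, normalize_motion
from .types import Motion, MotionDataset

__all__ = [
    "ActionPrediction",
    "CrossValReport",
    "pose_to_feature",
    "feature_to_pose",
    "motion_features",
    "aggregate_votes",
    "classify_motion",
    "stratified_kfold",
    "cross_validate",
]

logger = logging.getLogger(__name__)


@dataclass
class ActionPrediction:
    """Per-frame votes, per-class probability sums and the winning class."""

    frame_votes: list[int]
    prob_sums: np.ndarray
    predicted_class: str
    predicted_index: int
    tie_broken: bool = False
    scored_frames: list[int] = field(default_factory=list)


@dataclass
class CrossValReport:
    """Fold accuracies plus a pooled confusion matrix (rows = true class)."""

    fold_accuracies: list[float]
    mean_accuracy: float
    confusion_matrix: np.ndarray
    classes: tuple[str, ...]

    @property
    def pooled_accuracy(self) -> float:
        """Accuracy over all test predictions pooled across folds."""
        total = self.confusion_matrix.sum()
        return float(np.trace(self.confusion_matrix) / total) if total else 0.0


def pose_to_feature(pose: np.ndarray) -> np.ndarray:
    """Flatten a (J, 3) pose to a length-3J vector, joint-major order."""
    pose = np.asarray(pose, dtype=np.float64)
    return pose.reshape(-1)


def feature_to_pose(feature: np.ndarray) -> np.ndarray:
    """Inverse of :func:`pose_to_feature`."""
    feature = np.asarray(feature, dtype=np.float64)
    if feature.size % 3:
        raise ValueError(f"feature length {feature.size} not divisible by 3")
    return feature.reshape(-1, 3)


def motion_features(motion: Motion) -> np.ndarray:
    """Stack per-frame feature vectors into an (n, 3J) matrix."""
    return motion.frames.reshape(motion.n_frames, -1)


def aggregate_votes(
    probabilities: np.ndarray, class_names: tuple[str, ...]
) -> ActionPrediction:
    """Majority vote over per-frame class probabilities.

    Each row votes for its argmax class.  Vote-count ties are broken by
    the larger per-class probability sum, then by the lower class index;
    ``tie_broken`` is set whenever the vote alone was not decisive.
    """
    probabilities = np.asarray(probabilities, dtype=np.float64)
    if probabilities.ndim != 2 or probabilities.shape[0] < 1:
        raise ValueError("need a non-empty (n_frames, n_classes) matrix")
    votes = np.argmax(probabilities, axis=1)
    prob_sums = probabilities.sum(axis=0)
    counts = np.bincount(votes, minlength=probabilities.shape[1])
    leaders = np.flatnonzero(counts == counts.max())
    if leaders.size == 1:
        winner = int(leaders[0])
        tie_broken = False
    else:
        sums = prob_sums[leaders]
        winner = int(leaders[np.flatnonzero(sums == sums.max())[0]])
        tie_broken = True
    return ActionPrediction(
        frame_votes=[int(v) for v in votes],
        prob_sums=prob_sums,
        predicted_class=class_names[winner],
        predicted_index=winner,
        tie_broken=tie_broken,
    )


def classify_motion(
    params: NetworkParameters,
    motion: Motion,
    norm_config: NormalizationConfig = NormalizationConfig(),
    use_keyframes: bool = True,
    threshold: float = 30.0,
    k_policy: KPolicy = "fixed",
    normalize: bool = True,
) -> ActionPrediction:
    """Normalize, (optionally) summarize to keyframes, vote frame by frame.

    Ties in the vote count are broken by the larger per-class probability
    sum, then by the lower class index; ``tie_broken`` records whether the
    vote alone was not decisive.  ``normalize=False`` skips normalization
    (ablation support) — the method itself always normalizes first.
    """
    prepared = normalize_motion(motion, norm_config) if normalize else motion
    if use_keyframes:
        indices = extract_keyframes(prepared, threshold, k_policy).keyframes
    else:
        indices = list(range(prepared.n_frames))
    feats = motion_features(prepared)[indices]
    if feats.shape[1] != params.input_dim:
        raise ValueError(
            f"feature dim {feats.shape[1]} != network input_dim {params.input_dim}"
        )
    _, _, _, O = _batch_forward(params, feats)
    names = params.class_names or tuple(
        f"class{i}" for i in range(params.output_dim)
    )
    pred = aggregate_votes(O, names)
    pred.scored_frames = [int(i) for i in indices]
    return pred


def stratified_kfold(
    dataset: MotionDataset, folds: int = 5, seed: int = 0
) -> list[tuple[list[int], list[int]]]:
    """Seeded per-class round-robin fold assignment.

    Returns ``folds`` pairs of (train, test) motion indices; test folds are
    disjoint, cover the dataset, and are class-balanced within ±1.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    labels = np.array([m.label for m in dataset.motions])
    fold_of = np.empty(len(dataset.motions), dtype=np.int64)
    for cls in dataset.classes:
        idx = np.flatnonzero(labels == cls)
        if idx.size < folds:
            raise ValueError(
                f"class {cls!r} has {idx.size} motions, fewer than {folds} folds"
            )
        idx = idx[rng.permutation(idx.size)]
        fold_of[idx] = np.arange(idx.size) % folds
    out = []
    for f in range(folds):
        test = np.flatnonzero(fold_of == f)
        train_ = np.flatnonzero(fold_of != f)
        out.append(([int(i) for i in train_], [int(i) for i in test]))
    return out


def cross_validate(
    dataset: MotionDataset,
    net_config: NetworkConfig,
    norm_config: NormalizationConfig = NormalizationConfig(),
    use_keyframes: bool = True,
    threshold: float = 30.0,
    k_policy: KPolicy = "fixed",
    train_on_keyframes: bool = False,
    normalize: bool = True,
    folds: int = 5,
    seed: int = 0,
    frame_stride: int = 1,
) -> CrossValReport:
    """K-fold protocol: train per fold on frame features, test per motion.

    Training uses all frames of the training motions by default (keyframes
    only if ``train_on_keyframes``); testing always goes through
    :func:`classify_motion`.  ``frame_stride`` subsamples training frames
    to bound training cost; accuracy is motion-level.
    """
    if frame_stride < 1:
        raise ValueError("frame_stride must be >= 1")
    net_config = replace(net_config, output_dim=dataset.n_classes)
    R = dataset.n_classes
    confusion = np.zeros((R, R), dtype=np.int64)
    fold_accuracies: list[float] = []

    for f, (train_ids, test_ids) in enumerate(
        stratified_kfold(dataset, folds, seed)
    ):
        t0 = time.perf_counter()
        feats, labels = [], []
        for i in train_ids:
            m = dataset.motions[i]
            prepared = normalize_motion(m, norm_config) if normalize else m
            if train_on_keyframes:
                idx = extract_keyframes(prepared, threshold, k_policy).keyframes
            else:
                idx = list(range(0, prepared.n_frames, frame_stride))
            feats.append(motion_features(prepared)[idx])
            labels.append(
                np.full(len(idx), dataset.class_index(m.label), dtype=np.int64)
            )
        X = np.vstack(feats)
        y = np.concatenate(labels)
        params, report = train(X, y, net_config, class_names=dataset.classes)

        correct = 0
        for i in test_ids:
            m = dataset.motions[i]
            pred = classify_motion(
                params, m, norm_config, use_keyframes, threshold, k_policy,
                normalize=normalize,
            )
            true_idx = dataset.class_index(m.label)
            confusion[true_idx, pred.predicted_index] += 1
            correct += pred.predicted_index == true_idx
        acc = correct / len(test_ids)
        fold_accuracies.append(acc)
        logger.info(
            "fold %d: accuracy %.4f (%d/%d), %d train frames, "
            "%d epochs (%s), %.1f s",
            f, acc, correct, len(test_ids), X.shape[0],
            report.epochs_run, report.stop_reason, time.perf_counter() - t0,
        )

    return CrossValReport(
        fold_accuracies=fold_accuracies,
        mean_accuracy=float(np.mean(fold_accuracies)),
        confusion_matrix=confusion,
        classes=dataset.classes,
    )
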