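"""Independent brute-force oracles the library implementations are checked
against.  Everything here is deliberately naive: plain Python loops and a
line-by-line transcription of the iterative keyframe selection, sharing no
code with the package."""

import math


def naive_average_distance(a, b):
    """Double-loop mean Euclidean distance between paired joints."""
    total = 0.0
    n_joints = len(a)
    for j in range(n_joints):
        sq = 0.0
        for c in range(3):
            d = a[j][c] - b[j][c]
            sq += d * d
        total += math.sqrt(sq)
    return total / n_joints


def naive_nearest_neighbors(frames, query_index, k):
    """Exhaustive sort by (distance, index); query eligible."""
    ranked = sorted(
        (naive_average_distance(frames[query_index], pose), idx)
        for idx, pose in frames.items()
    )
    top = ranked[: min(k, len(ranked))]
    return [i for _, i in top], [d for d, _ in top]


def naive_extract_keyframes(frames, threshold, k_policy="fixed"):
    """Line-by-line transcription of the iterative selection loop.

    The query frame is pulled out of the pool first, its k nearest
    neighbors are found among the other remaining frames, those strictly
    under the threshold join the query as candidates, and the temporal
    lower-median candidate becomes the keyframe.  Returns (keyframes,
    candidate_sets) as parallel lists sorted by keyframe index.
    """
    n = len(frames)
    k_fixed = n // 2
    remaining = list(range(n))
    keyframes = []
    candidate_sets = []
    while remaining:
        query = remaining[0]
        if k_policy == "fixed":
            k = k_fixed
        else:
            k = len(remaining) // 2
        pool = {i: frames[i] for i in remaining[1:]}
        ranked = sorted(
            (naive_average_distance(frames[query], pose), idx)
            for idx, pose in pool.items()
        )
        phi = {query}
        for dist, idx in ranked[: min(k, len(ranked))]:
            if dist < threshold:
                phi.add(idx)
        phi = sorted(phi)
        keyframes.append(phi[(len(phi) - 1) // 2])
        candidate_sets.append(phi)
        remaining = [i for i in remaining if i not in phi]
    pairs = sorted(zip(keyframes, candidate_sets))
    return [kf for kf, _ in pairs], [phi for _, phi in pairs]


def finite_difference_gradients(loss_fn, matrices, eps=1e-5):
    """Central finite differences of loss_fn w.r.t. a list of matrices."""
    grads = []
    for m in matrices:
        g = [[0.0] * len(m[0]) for _ in range(len(m))]
        for i in range(len(m)):
            for j in range(len(m[0])):
                orig = m[i][j]
                m[i][j] = orig + eps
                up = loss_fn()
                m[i][j] = orig - eps
                down = loss_fn()
                m[i][j] = orig
                g[i][j] = (up - down) / (2.0 * eps)
        grads.append(g)
    return grads
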