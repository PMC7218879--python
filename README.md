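# skelact

Skeleton-based action recognition from 3D joint trajectories, built around
four stages:

1. **Normalization** — every pose is root-centered and rotated about the
   vertical (y) axis so the hip-to-hip vector lies along +z, removing
   position and heading while keeping how the motion is performed.
2. **Keyframe extraction** — an iterative nearest-neighbor summarizer: the
   earliest remaining frame queries its k = ⌊n/2⌋ nearest neighbors (mean
   per-joint Euclidean distance), neighbors strictly under a distance
   threshold form the candidate set together with the query, the temporal
   median candidate becomes a keyframe, and the whole set is discarded.
3. **Classification** — a from-scratch two-hidden-layer network (sigmoid
   hiddens, softmax output, cross-entropy loss) trained by hand-derived
   backpropagation with epoch-cap / vanishing-gradient / validation-patience
   stopping.
4. **Action score** — each scored (key)frame votes for its argmax class;
   the majority wins, with probability-sum then lowest-index tie-breaking.

A synthetic-motion generator produces labeled multi-class datasets whose
nuisance (random heading + translation drift + joint noise) is exactly what
normalization removes, so the full pipeline is testable offline.

## CLI

```sh
# generate a labeled synthetic dataset directory
skelact synth generate --out data/ --seed 42

# summarize one motion to keyframes (threshold default 30)
skelact keyframes data/class00/class00_m000.csv --threshold 30 --out kf.json

# train, predict, cross-validate
skelact train data/ --config run.yaml --out model.json
skelact predict model.json data/class00/class00_m000.csv --keyframes
skelact crossval data/ --config run.yaml --out report.json
```

Settings come from a flat YAML/JSON config file (see `skelact.cli.RunConfig`
for the full key list); command-line flags override file values. Exit codes:
0 success, 2 usage/config error, 1 runtime error.

## File formats

* **Motion CSV** — header `j00_x,j00_y,j00_z,…`, a `# fps=<float>` comment
  line, then one frame per row; floats are written at repr precision so
  round trips are bitwise lossless.
* **Dataset directory** — `<root>/<class_label>/<motion_id>.csv`.
* **Keyframe index / trained network** — deterministic JSON.

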