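# mgp — mirror/glass material-perception pipeline

An end-to-end, fully simulated re-implementation of a mirror-vs-glass
material perception modelling pipeline:

- **`mgp.synthetic`** — 64×64 RGB stimulus generator (band-pass noise
  textures with configurable appearance cues: vertical luminance
  gradient, contrast, saturation, mean luminance, second-order
  contrast-energy gradient, one-sided spatial cues) and simulated
  observers (5-point ratings, three-way judgments, recognizability
  votes, crowdworker sessions with catch-trial rejection).
- **`mgp.features`** — the 8-moment color-histogram features, a
  steerable-pyramid texture-statistic vector with a closed-form length
  formula, z-scoring and PCA reduction.
- **`mgp.classifiers`** — logistic-regression classifiers over the
  hand-engineered features and a parametric depth-1..12 CNN family
  (conv / batch-norm / ReLU / max-pool blocks, dense or global-average-
  pooled head) implemented in pure NumPy, trained with SGD + momentum
  and early stopping; repeated two-fold cross-validation scoring.
- **`mgp.diagnostic`** — the five-round diagnostic image-set
  construction (three-way screening with per-cell quotas, crowdsourced
  conflict selection, lab confirmation, recognizability screening,
  per-bin quota sampling among consistent images) and flat/decorrelated
  set assembly.
- **`mgp.hyperopt`** — hyperparameter search (Gaussian-process
  surrogate with expected improvement, or random fallback) whose
  objective is the Pearson correlation between model scores and
  simulated-observer mean ratings on held-out diagnostic images, plus
  multi-instance validation and a depth sweep.
- **`mgp.rsa`** — two-stage representational similarity analysis
  (score RDMs, 1−r classifier dissimilarity matrices with random
  controls, classical MDS, leave-one-out noise ceiling, layer-wise
  dissimilarity).
- **`mgp.interpret`** — class activation maps (GAP-head models),
  vertical-profile analysis, noise-robustness curves and the vertical
  inversion test.
- **`mgp.scenarios`** — reference simulation scenarios: planted-count
  scenarios for the per-round selection quotas and a desk-scale
  end-to-end pipeline run.
- **`mgp.cli` / `mgp.config` / `mgp.manifest`** — stage orchestration
  with full seed/config provenance.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact
pipeline counts, oracle-equivalence checks, parameter recovery,
depth-sweep / noise-robustness / CAM / inversion analogues); the
depth-sweep test trains ~180 small CNNs and takes several minutes.

## CLI

One command per stage plus an end-to-end runner:

```bash
mgp generate|rate|features|train|diagnose|search|rsa|interpret|run-all \
    --config config.yaml --seed 1 --out outdir/
```

Stages read upstream artifacts from `--out` and fail with an actionable
error naming the stage to run first. Every artifact is a CSV/JSON/PNG
with a `.meta.json` sidecar recording the config hash, seed and package
version. `config.yaml` is a YAML rendering of `mgp.config.RunConfig`;
any subset of fields may be given.

```bash
mgp run-all --seed 1 --out /tmp/mgp-demo
```

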