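# cytocoral

A toolkit for multi-class (Bethesda: NILM / LSIL / HSIL / SCC) classification
of multi-cell liquid-Pap cytology images, exercised end-to-end on synthetic
microscopy-style images:

- **`cytocoral.imagesim`** — seeded synthetic 4-class multi-cell image
  generator with ground-truth cytoplasm/nucleus masks and a configurable
  cross-preparation domain shift (stain hue, contrast, cell density,
  background noise).
- **`cytocoral.datasets`** — manifest-backed datasets (CSV + PNG),
  rotation/flip augmentation with duplicate avoidance, class balancing to
  the largest class, per-class stratified 65:15:20 splitting.
- **`cytocoral.nets`** — a small numpy neural-network stack (conv /
  ReLU / 2×2 max-pool / dense / dropout with manual backprop), reference
  architectures pinned to exact trainable-parameter budgets (compact CNN
  60,772; autoencoder 20,355; compressed-feature classifier 10,292; AE-CNN
  total 30,647), a brute-force budget solver, a stub transfer backbone with
  head replacement, and Adam training loops.
- **`cytocoral.ensemble`** — majority voting with a deterministic,
  documented tie rule.
- **`cytocoral.coral`** — batch covariance, CORAL loss (with analytic
  gradients), joint loss and the shared-weight two-stream unsupervised
  domain-adaptation trainer, plus grid tuning of the adaptation weight.
- **`cytocoral.evalmetrics`** — confusion matrices, classification reports
  (accuracy / precision / recall / F1 / FPR / FNR), one-vs-rest ROC/AUC,
  Bethesda→binary grouping, multi-run consistency summaries and gradient
  saliency maps.
- **`cytocoral.cli` / `cytocoral.experiment`** — a `cytocoral` command with
  subcommands for every stage and a YAML-driven full pipeline.

Everything is seeded and deterministic under single-threaded numpy; no deep
learning framework is required.

## CLI

```sh
cytocoral simulate --counts NILM=613,LSIL=113,HSIL=163,SCC=74 \
    --domain source --seed 1 --out data/source
cytocoral augment --manifest data/source/manifest.csv --out data/balanced --seed 2
cytocoral split --manifest data/balanced/manifest.csv --seed 3
cytocoral train --manifest data/balanced/manifest.csv --epochs 10 --out runs/cnn
cytocoral adapt --source data/balanced/manifest.csv \
    --target data/target/manifest.csv --lambda auto --seed 4 --out runs/adapted
cytocoral ensemble-eval --models m1.npz,m2.npz,m3.npz --manifest data/balanced/manifest.csv
cytocoral evaluate --checkpoint runs/cnn/checkpoint.npz --manifest data/balanced/manifest.csv
cytocoral consistency --manifest data/balanced/manifest.csv --runs 5
cytocoral saliency --checkpoint runs/cnn/checkpoint.npz \
    --manifest data/balanced/manifest.csv --index 0 --out sal.png
cytocoral run --config experiment.yaml --out runs/full
```

A minimal experiment config:

```yaml
seed: 5
image_size: 32
dataset:
  counts: {NILM: 40, LSIL: 24, HSIL: 24, SCC: 24}
model: cnn            # cnn | ae_cnn | transfer_stub | ensemble
training: {epochs: 5, learning_rate: 0.001, batch_size: 16}
```

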