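# chromastate

Unsupervised cell-state analysis of chromatin microscopy images, exercised
end-to-end on a seeded synthetic tissue-core generator:

- **synth** — synthetic cohorts (patients, tissue-core samples, planted
  nuclear states, duct masks, rendered chromatin/cytokeratin channels) with
  controllable state proportions per phenotypic category, same-state spatial
  assortativity, and per-state duct affinity.
- **imaging** — percentile range normalization, intensity/noise
  augmentations, Otsu + connected-component duct segmentation, a classical
  watershed stand-in nucleus segmenter, and masked 96×96 patch extraction.
- **representation** — a pure-NumPy convolutional variational autoencoder
  (5 strided conv layers, mean/log-variance heads, mirrored decoder) that
  embeds nucleus patches; embeddings are posterior means.
- **states** — balanced per-category downsampling, PCA + mini-batch k-means
  into 8 cell states (canonically ordered by mean nucleus area),
  inertia-guided subclustering, held-out assignment, composition tables.
- **morphometrics** — ~50 named nuclear morphology / chromatin organization
  features (size, shape, radius, curvature, moments, texture, intensity),
  per-cluster Welch tests with Benjamini–Hochberg correction, default
  selection thresholds (FDR < 0.01, fold change outside [0.8, 1.2],
  |mean z| > 0.5), and correlation-graph feature grouping.
- **spatial** — duct distances (natural-log pixel transform; 0.18 µm/px),
  neighborhood composition within a 25.9 µm radius, per-sample 8×8
  co-localization matrices, and a within-sample label-permutation null with
  fold changes.
- **classify** — 3-hidden-layer MLP classifiers (leaky ReLU, dropout 0.5,
  inverse-class-frequency weighted cross-entropy), leave-one-patient-out
  cross-validation with stage-level error types, cluster-ablation studies,
  misclassification contrasts, and a logistic-regression baseline.

No GPU or deep-learning framework is required; the neural networks are
implemented in NumPy with manual backpropagation (`chromastate._nn`) and are
deterministic for a fixed seed on a single worker.

## CLI

```sh
chromastate synth --config configs/desk_cohort.yaml --out scratch/cohort --seed 1
chromastate segment --chromatin scratch/cohort/sample000_chromatin.tif \
    --cytokeratin scratch/cohort/sample000_cytokeratin.tif --out scratch/seg
chromastate vae-train --patches scratch/seg/sample000_patches.npy \
    --out scratch/vae.npz --latent-dim 32 --epochs 16
chromastate vae-encode --patches scratch/seg/sample000_patches.npy \
    --checkpoint scratch/vae.npz --out scratch/latents.csv
chromastate cluster --latents scratch/latents.csv --out scratch/clusters
chromastate coloc --cells cells.csv --out coloc.json --radius-um 25.9 \
    --shuffles 2000 --seed 0
```

## Notes on scale

Defaults are desk-scale (hundreds to ~1200 nuclei per cohort, latent
dimension 32–64, ~16 VAE epochs) so everything runs in minutes on one CPU.
Reference configurations at full training scale (latent
6000, batch 8000, 310 epochs; 24,224 balanced cells per category) are
constructible (`VAEConfig.paper_scale()`, `balanced_downsample`) but not
meant to be trained here.
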