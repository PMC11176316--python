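# asd-swnet

A shared-weight pipeline for classifying subjects from resting-state
functional-connectivity features:

1. **Connectivity features** — per-subject Pearson correlation between ROI
   time series, flattened over the strict upper triangle
   (`S = n(n-1)/2`; 19,900 features for a 200-ROI atlas), with optional
   recursive feature elimination.
2. **EROS data augmentation** — SMOTE-style interpolation of feature
   vectors, where each sample's nearest neighbours are found with the EROS
   multivariate time-series distance
   (`sqrt(2 - 2 * sum_i w_i |<a_i, b_i>|)` over paired covariance
   eigenvectors, with eigenvalue-derived weights `w` summing to 1).
3. **Denoising autoencoder** — unsupervised pretraining with additive
   Gaussian input noise; a dense encoder compresses the feature vector to a
   bottleneck (2,000 units at full scale).
4. **Shared-weight 1-D CNN** — the pretrained encoder is prepended to a
   seven-convolution CNN (valid convolutions, max pooling, selective batch
   normalization, dropout, sigmoid head) and the whole model is trained
   jointly with binary cross-entropy.
5. **Evaluation** — nested k-fold, leave-one-out and leave-one-site-out
   cross-validation with per-fold refitting of every stage (including
   augmentation and pretraining), a leakage guard, the standard metric
   suite, and paired t-tests for model comparison.

A synthetic-cohort generator (`asd_swnet.synthetic_cohort`) produces
two-class multivariate Gaussian time series with controlled between-class
correlation differences and optional per-site shifts, so the entire
pipeline is testable end to end without any external data.

The neural-network stages are implemented on NumPy with manual
backpropagation (`asd_swnet._nn`): dense and 1-D conv layers, batch
normalization, max pooling, dropout, SGD-with-momentum and Adam. No deep
learning framework is required.

## CLI

```bash
# generate a synthetic cohort (per-subject TSVs + phenotypes.csv)
asd-swnet simulate --config sim.yaml --out data/

# Pearson-FC feature vectors (optionally RFE-reduced to 2000)
asd-swnet features --data data/ --out features.tsv [--rfe 2000]

# EROS-kNN augmentation (k neighbours, gamma-fold growth)
asd-swnet augment --data data/ --features features.tsv \
    --k 5 --gamma 2 --seed 0 --out augmented/

# denoising-autoencoder pretraining
asd-swnet pretrain --features features.tsv --config cfg.yaml --out dae.ckpt

# shared-weight joint training
asd-swnet train --features features.tsv --labels data/phenotypes.csv \
    --dae dae.ckpt --config cfg.yaml --out model.ckpt

# cross-validated evaluation (nested | loocv | loso)
asd-swnet evaluate --data data/ --scheme nested --config cfg.yaml \
    --seed 0 --out report.json
```

Config YAML files use `dae:`, `cnn:` and `augmentation:` sections whose
keys mirror the config dataclasses (`DaeConfig`, `CnnConfig`,
`AugmentationConfig`). Defaults follow the full-scale hyperparameters:
SGD momentum 0.9 and learning rate 1e-4 with Gaussian noise 0.1 for the
DAE; Adam at 1e-4, dropout 0.3, 200 epochs with early-stopping patience 20
for the CNN; k=5 neighbours and gamma=2 for augmentation.

## Data formats

- **Time series**: delimited text (TSV default), one subject per file,
  rows = timepoints, columns = ROIs (`--transpose` for the other
  orientation). Files with missing or non-numeric cells are rejected and
  the subject excluded (logged).
- **Phenotypes**: CSV with header `subject_id,label,site_id`
  (patient = 1, control = 0).
- **Reports**: versioned JSON with per-fold metrics and aggregates.
- **Checkpoints**: single-file `.npz` archives embedding the full config.

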