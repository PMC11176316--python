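"""Evaluation protocols: nested k-fold, LOOCV and leave-one-site-out
cross-validation, the metric suite, and paired statistical comparison.

The protocol runner refits *everything* per outer fold — EROS weights,
optional RFE, augmentation, DAE pretraining and joint training all see the
training subjects only — and a leakage guard raises if any test subject is
found in a fitting or augmentation step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .connectivity import compute_features, rfe_select
from .dae import DaeConfig, DenoisingAutoencoder
from .data_io import Dataset, PhenotypeTable
from .eros_augment import AugmentationConfig, augment, is_synthetic
from .errors import ConfigError, DimensionError, LeakageError
from .swnet_classifier import CnnConfig, build_swnet, train_joint

logger = logging.getLogger(__name__)

SCHEMES = ("nested_kfold", "loocv", "leave_one_site_out")
METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc")


@dataclass(frozen=True)
class FoldPlan:
    """Per-outer-fold (train, validation, test) subject-id splits."""

    folds: tuple[tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]], ...]
    scheme: str
    n_outer: int
    seed: int

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ConfigError(f"unknown scheme {self.scheme!r}")
        seen_test: set[str] = set()
        for train, val, test in self.folds:
            tr, va, te = set(train), set(val), set(test)
            if tr & te or va & te:
                raise LeakageError("test ids overlap train/validation ids")
            if seen_test & te:
                raise LeakageError("test sets are not pairwise disjoint")
            seen_test |= te

    def __len__(self) -> int:
        return len(self.folds)


@dataclass
class EvalReport:
    """Per-fold metric records plus arithmetic-mean/sd aggregates."""

    folds: list[dict]
    aggregate: dict
    config: dict
    seed: int


def make_folds(pheno: PhenotypeTable, scheme: str, n_outer: int = 10,
               seed: int = 0, inner_val_fraction: float = 1.0 / 9.0,
               ) -> FoldPlan:
    """Build a FoldPlan whose test sets partition the cohort.

    For the nested scheme the outer folds are label-stratified and an inner
    validation split (one ninth of the outer-train set by default) is carved
    for model selection / early stopping.  LOOCV uses one subject per test
    fold; the site scheme holds out one acquisition site per fold.
    """
    ids = list(pheno.subject_ids)
    labels = pheno.labels
    rng = np.random.default_rng(seed)

    if scheme == "nested_kfold":
        if len(ids) < n_outer:
            raise ConfigError(f"{len(ids)} subjects < {n_outer} folds")
        skf = StratifiedKFold(n_splits=n_outer, shuffle=True,
                              random_state=seed)
        folds = []
        for train_idx, test_idx in skf.split(np.zeros(len(ids)), labels):
            train_ids = [ids[i] for i in train_idx]
            train_lab = labels[train_idx]
            val_ids = _carve_validation(train_ids, train_lab,
                                        inner_val_fraction, rng)
            tr = tuple(s for s in train_ids if s not in set(val_ids))
            folds.append((tr, tuple(val_ids),
                          tuple(ids[i] for i in test_idx)))
        return FoldPlan(tuple(folds), scheme, n_outer, seed)

    if scheme == "loocv":
        folds = []
        for i, sid in enumerate(ids):
            train_ids = [s for j, s in enumerate(ids) if j != i]
            train_lab = np.delete(labels, i)
            val_ids = _carve_validation(train_ids, train_lab,
                                        inner_val_fraction, rng)
            tr = tuple(s for s in train_ids if s not in set(val_ids))
            folds.append((tr, tuple(val_ids), (sid,)))
        return FoldPlan(tuple(folds), scheme, len(ids), seed)

    if scheme == "leave_one_site_out":
        sites = sorted(set(pheno.site_ids))
        if len(sites) < 2:
            raise ConfigError("leave-one-site-out needs >= 2 sites")
        if any(not s for s in pheno.site_ids):
            raise ConfigError("empty site_id with site scheme requested")
        folds = []
        for site in sites:
            test_ids = tuple(s for s, g in zip(ids, pheno.site_ids)
                             if g == site)
            train_ids = [s for s, g in zip(ids, pheno.site_ids) if g != site]
            train_lab = np.array([pheno.label_of(s) for s in train_ids])
            val_ids = _carve_validation(train_ids, train_lab,
                                        inner_val_fraction, rng)
            tr = tuple(s for s in train_ids if s not in set(val_ids))
            folds.append((tr, tuple(val_ids), test_ids))
        return FoldPlan(tuple(folds), scheme, len(sites), seed)

    raise ConfigError(f"unknown scheme {scheme!r}")


def _carve_validation(train_ids: list[str], train_labels: np.ndarray,
                      fraction: float, rng: np.random.Generator) -> list[str]:
    val: list[str] = []
    for cls in np.unique(train_labels):
        cls_ids = [s for s, l in zip(train_ids, train_labels) if l == cls]
        n_val = max(1, int(round(fraction * len(cls_ids))))
        if n_val >= len(cls_ids):
            n_val = max(0, len(cls_ids) - 1)
        picked = rng.permutation(len(cls_ids))[:n_val]
        val.extend(cls_ids[i] for i in picked)
    return sorted(val)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def pairwise_auc(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """P(random positive outranks random negative), ties counted 1/2."""
    pos = y_prob[y_true == 1]
    neg = y_prob[y_true == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ConfigError("AUC undefined: only one class present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def compute_metrics(y_true: Sequence[int], y_prob: Sequence[float],
                    threshold: float = 0.5) -> dict:
    """Accuracy/precision/recall/F1 from the thresholded confusion table
    (positive = patient, tie at the threshold predicts positive) plus the
    pairwise-definition AUC.

    With zero predicted positives, precision is reported as 0 with the
    ``precision_undefined`` flag set so aggregates stay finite.
    """
    y_true = np.asarray(y_true).astype(np.int64)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    if y_true.shape != y_prob.shape:
        raise DimensionError("y_true and y_prob differ in length")
    y_pred = (y_prob >= threshold).astype(np.int64)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    record = {
        "accuracy": (tp + tn) / len(y_true),
        "recall": tp / (tp + fn) if (tp + fn) else 0.0,
        "precision_undefined": (tp + fp) == 0,
        "n": int(len(y_true)),
    }
    record["precision"] = tp / (tp + fp) if (tp + fp) else 0.0
    denom = 2 * tp + fp + fn
    record["f1"] = 2 * tp / denom if denom else 0.0
    record["auc"] = pairwise_auc(y_true, y_prob)
    return record


def compare_models(metrics_a: Sequence[float], metrics_b: Sequence[float],
                   alpha: float = 0.01) -> dict:
    """Paired two-sided Student's t-test on per-fold metrics."""
    a = np.asarray(metrics_a, dtype=np.float64)
    b = np.asarray(metrics_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise DimensionError("paired t-test needs equal-length vectors")
    if len(a) < 2:
        raise ConfigError("need >= 2 folds for a paired t-test")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        # degenerate: all differences identical
        mean = diff.mean()
        t = 0.0 if mean == 0 else np.inf * np.sign(mean)
        p = 1.0 if mean == 0 else 0.0
        return {"t": float(t), "p": float(p), "significant": p < alpha,
                "degenerate": True}
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "significant": bool(p < alpha),
            "degenerate": False}


# ---------------------------------------------------------------------------
# full pipeline per fold
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything one outer fold needs to refit the full pipeline."""

    augmentation: AugmentationConfig = field(
        default_factory=AugmentationConfig)
    dae: DaeConfig = field(default_factory=DaeConfig)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    rfe_target: int | None = None     # optional RFE path
    standardize: bool = True          # z-score features on train statistics
    threshold: float = 0.5
    seed: int = 0

    def snapshot(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


def run_protocol(dataset: Dataset, plan: FoldPlan,
                 config: PipelineConfig) -> EvalReport:
    """Run the full pipeline over every fold of the plan.

    Per fold: feature computation (per subject, fit-free), optional RFE on
    train only, EROS weights + augmentation of the train fold only, DAE
    pretraining, shared-weight assembly and joint training with the fold's
    validation split for early stopping, then metrics on the untouched test
    subjects.  Deterministic given the seeds in ``config``.
    """
    if dataset.features is None:
        dataset = compute_features(dataset)
    all_ids = set(dataset.phenotypes.subject_ids)

    fold_records: list[dict] = []
    for fold_idx, (train_ids, val_ids, test_ids) in enumerate(plan.folds):
        _leakage_check(train_ids, val_ids, test_ids, all_ids)
        y_prob, y_true = _run_fold(dataset, list(train_ids), list(val_ids),
                                   list(test_ids), config, fold_idx)
        record = compute_metrics(y_true, y_prob, config.threshold)
        record["fold"] = fold_idx
        fold_records.append(record)
        logger.info("fold %d: %s", fold_idx,
                    {k: round(record[k], 4) for k in METRIC_NAMES
                     if k in record})

    aggregate = {}
    for name in METRIC_NAMES:
        vals = np.array([r[name] for r in fold_records], dtype=np.float64)
        aggregate[f"{name}_mean"] = float(vals.mean())
        aggregate[f"{name}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 \
            else 0.0
    return EvalReport(folds=fold_records, aggregate=aggregate,
                      config=config.snapshot(), seed=config.seed)


def _leakage_check(train_ids, val_ids, test_ids, all_ids) -> None:
    tr, va, te = set(train_ids), set(val_ids), set(test_ids)
    if (tr | va) & te:
        raise LeakageError("test subjects present in the training fold")
    if not te <= all_ids or not tr <= all_ids:
        raise LeakageError("fold references unknown subjects")


def _run_fold(dataset: Dataset, train_ids: list[str], val_ids: list[str],
              test_ids: list[str], config: PipelineConfig,
              fold_idx: int) -> tuple[np.ndarray, np.ndarray]:
    fold_seed = config.seed * 10_007 + fold_idx
    pheno = dataset.phenotypes

    train_pheno = pheno.subset(train_ids)
    train_pheno.require_both_classes()

    # train-only sub-dataset for augmentation (leakage guard: synthetic
    # sources can only be training subjects)
    train_ds = Dataset(
        phenotypes=train_pheno,
        series={s: dataset.series[s] for s in train_ids},
        features={s: dataset.features[s] for s in train_ids})
    aug_cfg = AugmentationConfig(
        k=config.augmentation.k, gamma=config.augmentation.gamma,
        phi_range=config.augmentation.phi_range,
        same_class_only=config.augmentation.same_class_only,
        seed=fold_seed)
    augmented = augment(train_ds, aug_cfg)
    for sid in augmented.phenotypes.subject_ids:
        if not is_synthetic(sid) and sid not in set(train_ids):
            raise LeakageError(f"augmentation source {sid} outside the "
                               "training fold")

    aug_ids = list(augmented.phenotypes.subject_ids)
    x_train = augmented.feature_matrix(aug_ids)
    y_train = augmented.labels_for(aug_ids)
    x_val = dataset.feature_matrix(val_ids)
    y_val = dataset.labels_for(val_ids)
    x_test = dataset.feature_matrix(test_ids)
    y_test = dataset.labels_for(test_ids)

    if config.rfe_target is not None:
        sel = rfe_select(x_train, y_train, config.rfe_target,
                         seed=fold_seed)
        cols = np.array(sel.selected_indices)
        x_train, x_val, x_test = (x_train[:, cols], x_val[:, cols],
                                  x_test[:, cols])

    if config.standardize:
        mu = x_train.mean(axis=0)
        sd = x_train.std(axis=0)
        sd[sd == 0] = 1.0
        x_train = (x_train - mu) / sd
        x_val = (x_val - mu) / sd
        x_test = (x_test - mu) / sd

    from dataclasses import replace
    dae_cfg = replace(config.dae, input_dim=x_train.shape[1],
                      seed=fold_seed)
    dae_model = DenoisingAutoencoder(dae_cfg)
    dae_model.fit(x_train)

    cnn_cfg = replace(config.cnn, input_length=dae_cfg.bottleneck_dim,
                      seed=fold_seed)
    model = build_swnet(dae_model.encoder, cnn_cfg)
    model, _ = train_joint(model, x_train, y_train, cnn_cfg,
                           val_data=(x_val, y_val))

    y_prob = np.atleast_1d(model.predict_proba(x_test))
    return y_prob, y_test
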