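"""Functional-connectivity features: Pearson FC matrix, upper-triangle
vectorization, and recursive feature elimination.

The feature vector ordering is fixed package-wide as row-major over the
strict upper triangle (i < j, i ascending then j), i.e. the order produced
by ``numpy.triu_indices(n, 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import LinearSVC

from .data_io import Dataset, RoiTimeSeries
from .errors import ConfigError, DimensionError, FormatError

SYMMETRY_TOL = 1e-8


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric unit-diagonal matrix of pairwise Pearson coefficients."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DimensionError("FC matrix must be square")
        object.__setattr__(self, "values", v)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FeatureVector:
    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise DimensionError("feature vector must be 1-D")
        if not np.isfinite(v).all():
            raise FormatError(f"{self.subject_id}: non-finite feature values")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FeatureSelection:
    selected_indices: tuple[int, ...]
    target_count: int
    ranking_seed: int

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.selected_indices)
        if len(idx) != self.target_count:
            raise ConfigError("selection size differs from target_count")
        if len(set(idx)) != len(idx):
            raise ConfigError("selected indices must be unique")
        object.__setattr__(self, "selected_indices", idx)


def n_pairs(n_rois: int) -> int:
    """Number of strict upper-triangle entries, S = n(n-1)/2."""
    return n_rois * (n_rois - 1) // 2


def pearson_fc(ts: RoiTimeSeries, strict: bool = True) -> FCMatrix:
    """Pairwise Pearson correlation between ROI columns.

    In strict mode a zero-variance column is an error naming the ROI; in
    lenient mode its coefficients are set to 0 with a warning.
    """
    x = ts.values
    if x.shape[0] < 3:
        raise DimensionError(f"{ts.subject_id}: need T >= 3 for correlation")
    stds = x.std(axis=0)
    dead = np.flatnonzero(stds == 0)
    if dead.size and strict:
        names = (", ".join(ts.roi_labels[i] for i in dead)
                 if ts.roi_labels else ", ".join(map(str, dead.tolist())))
        raise FormatError(
            f"{ts.subject_id}: zero-variance ROI column(s): {names}")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    if dead.size:
        warnings.warn(f"{ts.subject_id}: zero-variance ROI(s) "
                      f"{dead.tolist()}; coefficients set to 0")
        corr[dead, :] = 0.0
        corr[:, dead] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return FCMatrix(ts.subject_id, corr)


def vectorize_upper(fc: FCMatrix) -> FeatureVector:
    """Flatten the strict upper triangle row-major into a length-S vector."""
    v = fc.values
    if np.abs(v - v.T).max() > SYMMETRY_TOL:
        raise FormatError(f"{fc.subject_id}: matrix asymmetric beyond "
                          f"{SYMMETRY_TOL}")
    iu = np.triu_indices(fc.n_rois, k=1)
    return FeatureVector(fc.subject_id, v[iu])


def matrix_from_vector(vec: FeatureVector, n_rois: int) -> FCMatrix:
    """Inverse of :func:`vectorize_upper` for symmetric unit-diagonal input."""
    if len(vec) != n_pairs(n_rois):
        raise DimensionError(
            f"vector length {len(vec)} != n(n-1)/2 for n={n_rois}")
    mat = np.eye(n_rois)
    iu = np.triu_indices(n_rois, k=1)
    mat[iu] = vec.values
    mat[(iu[1], iu[0])] = vec.values
    return FCMatrix(vec.subject_id, mat)


def compute_features(dataset: Dataset, strict: bool = True) -> Dataset:
    """Attach upper-triangle FC feature vectors to every subject."""
    features = {
        sid: vectorize_upper(pearson_fc(ts, strict=strict)).values
        for sid, ts in dataset.series.items()
    }
    return Dataset(phenotypes=dataset.phenotypes, series=dataset.series,
                   features=features)


def rfe_select(features: np.ndarray, labels: np.ndarray, target_count: int,
               step: int | None = None, seed: int = 0) -> FeatureSelection:
    """Recursive feature elimination with a linear max-margin ranker.

    Refits a linear SVM each round and removes the ``step`` features with
    the smallest absolute coefficients until ``target_count`` remain.  When
    ``step`` is None, 2% of the remaining features (at least 1) are removed
    per round.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    n_sub, n_feat = features.shape
    if target_count >= n_feat:
        raise ConfigError(f"target_count {target_count} must be < number of "
                          f"features {n_feat}")
    if target_count < 1:
        raise ConfigError("target_count must be positive")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ConfigError("RFE needs both classes present")
    if counts.min() < 2:
        raise ConfigError("RFE needs at least 2 subjects per class")
    if step is not None and step < 1:
        raise ConfigError("step must be a positive integer")

    # canonicalize subject order so the selection is invariant to row
    # permutations of the input (the solver is order-sensitive)
    order = sorted(range(n_sub),
                   key=lambda i: (int(labels[i]), features[i].tobytes()))
    features = features[order]
    labels = labels[order]

    remaining = np.arange(n_feat)
    while remaining.size > target_count:
        model = LinearSVC(C=1.0, dual=True, max_iter=5000, tol=1e-4,
                          random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(features[:, remaining], labels)
        ranks = np.abs(model.coef_.ravel())
        n_drop = step if step is not None else max(1, remaining.size // 50)
        n_drop = min(n_drop, remaining.size - target_count)
        # drop lowest |coef|; stable order for determinism
        order = np.argsort(ranks, kind="stable")
        remaining = np.delete(remaining, order[:n_drop])

    return FeatureSelection(tuple(sorted(remaining.tolist())),
                            target_count=target_count, ranking_seed=seed)
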