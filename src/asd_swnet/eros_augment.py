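"""EROS-distance data augmentation.

The augmentation creates SMOTE-style synthetic feature vectors, but finds
each sample's nearest neighbours with a multivariate time-series distance
rather than Euclidean distance on the features:

* per subject, the eigendecomposition of the n x n column covariance of the
  ROI time series;
* a weight vector ``omega`` derived from the cohort's normalized
  eigenvalue spectra (sums to 1);
* similarity ``EROS(A, B, omega) = sum_i omega_i * |<a_i, b_i>|`` over paired
  eigenvectors, and distance ``sqrt(2 - 2 * EROS)``;
* synthetic vectors ``x' = x + phi * (x_hat - x)`` interpolated toward a
  randomly chosen neighbour, with ``phi`` uniform on a sub-interval of
  [0, 1].

The absolute value in the similarity makes the eigenvector sign ambiguity
harmless; no sign canonicalization is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import Dataset, PhenotypeTable, RoiTimeSeries
from .errors import ConfigError, DimensionError, NumericalError

_ORTHO_TOL = 1e-8
_RADICAND_TOL = 1e-10


@dataclass(frozen=True)
class EigenStructure:
    """Eigenvectors/eigenvalues of one subject's ROI covariance matrix."""

    subject_id: str
    eigenvectors: np.ndarray  # n x n, orthonormal columns
    eigenvalues: np.ndarray   # length n, nonnegative, descending

    def __post_init__(self) -> None:
        vecs = np.asarray(self.eigenvectors, dtype=np.float64)
        vals = np.asarray(self.eigenvalues, dtype=np.float64)
        n = vecs.shape[0]
        if vecs.shape != (n, n) or vals.shape != (n,):
            raise DimensionError("eigenstructure shapes inconsistent")
        gram = vecs.T @ vecs
        if np.abs(gram - np.eye(n)).max() > _ORTHO_TOL:
            raise NumericalError("eigenvector columns not orthonormal")
        if np.any(np.diff(vals) > 1e-12):
            raise NumericalError("eigenvalues must be sorted descending")
        if vals.min() < -1e-10:
            raise NumericalError("negative eigenvalue")
        object.__setattr__(self, "eigenvectors", vecs)
        object.__setattr__(self, "eigenvalues", np.clip(vals, 0.0, None))

    @property
    def n(self) -> int:
        return self.eigenvectors.shape[0]


@dataclass(frozen=True)
class ErosWeights:
    """Nonnegative weights over eigenvector indices, summing to 1."""

    omega: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.omega, dtype=np.float64)
        if w.ndim != 1:
            raise DimensionError("omega must be a vector")
        if w.min() < 0:
            raise NumericalError("omega entries must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-10:
            raise NumericalError("omega must sum to 1")
        object.__setattr__(self, "omega", w)

    def __len__(self) -> int:
        return len(self.omega)


@dataclass(frozen=True)
class AugmentationConfig:
    k: int = 5
    gamma: int = 2
    phi_range: tuple[float, float] = (0.0, 1.0)
    same_class_only: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.gamma < 1:
            raise ConfigError("gamma must be >= 1")
        lo, hi = self.phi_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ConfigError("phi_range must be an interval within [0,1]")


def covariance_eigen(ts: RoiTimeSeries) -> EigenStructure:
    """Eigendecomposition (via SVD) of the n x n column covariance."""
    x = ts.values
    if x.shape[0] < 2:
        raise DimensionError(f"{ts.subject_id}: need T >= 2 for covariance")
    centered = x - x.mean(axis=0)
    if np.abs(centered).max() == 0.0:
        raise NumericalError(f"{ts.subject_id}: all-constant series, "
                             "covariance degenerate")
    cov = (centered.T @ centered) / (x.shape[0] - 1)
    # SVD of a symmetric PSD matrix = eigendecomposition, singular values
    # already descending
    u, s, _ = np.linalg.svd(cov, hermitian=True)
    return EigenStructure(ts.subject_id, u, s)


def eros_weights(eigs: list,
                 aggregate: str = "mean") -> ErosWeights:
    """omega from per-subject sum-normalized spectra, aggregated cohort-wide.

    Each subject's eigenvalues are normalized to sum 1, the normalized
    spectra are combined componentwise by the aggregation function, and the
    aggregate is renormalized to sum 1.  Items may be
    :class:`EigenStructure` instances or raw eigenvalue vectors.
    """
    if not eigs:
        raise ConfigError("need at least one eigenstructure")
    raw = [e.eigenvalues if isinstance(e, EigenStructure)
           else np.asarray(e, dtype=np.float64) for e in eigs]
    n = len(raw[0])
    if any(len(v) != n for v in raw):
        raise DimensionError("eigenstructures have inconsistent n")
    spectra = np.stack([v / v.sum() for v in raw])
    if aggregate == "mean":
        agg = spectra.mean(axis=0)
    elif aggregate == "max":
        agg = spectra.max(axis=0)
    elif aggregate == "min":
        agg = spectra.min(axis=0)
    else:
        raise ConfigError(f"unknown aggregation {aggregate!r}")
    total = agg.sum()
    if total <= 0:
        raise NumericalError("aggregated spectrum sums to zero")
    return ErosWeights(agg / total)


def eros_similarity(a: EigenStructure, b: EigenStructure,
                    w: ErosWeights) -> float:
    """Weighted sum of |cos theta_i| between paired eigenvectors; in [0,1]."""
    if a.n != b.n or len(w) != a.n:
        raise DimensionError("dimension mismatch between eigenstructures "
                             "and weights")
    cosines = np.abs(np.einsum("ij,ij->j", a.eigenvectors, b.eigenvectors))
    return float(np.dot(w.omega, cosines))


def eros_distance(a: EigenStructure, b: EigenStructure,
                  w: ErosWeights) -> float:
    """sqrt(2 - 2 * EROS similarity); 0 for identical structures."""
    radicand = 2.0 - 2.0 * eros_similarity(a, b, w)
    if radicand < -_RADICAND_TOL:
        raise NumericalError(f"negative radicand {radicand}: weights or "
                             "eigenvectors are inconsistent")
    return float(np.sqrt(max(radicand, 0.0)))


def spca_similarity(a: EigenStructure, b: EigenStructure, z: int) -> float:
    """Sum of squared cosines over the leading z x z principal-axis pairs."""
    if z < 1 or z > a.n:
        raise DimensionError(f"z must be in [1, {a.n}], got {z}")
    if a.n != b.n:
        raise DimensionError("dimension mismatch")
    cos = a.eigenvectors[:, :z].T @ b.eigenvectors[:, :z]
    return float(np.sum(cos * cos))


def knn_eros(query_id: str, dataset: Dataset, w: ErosWeights, k: int,
             same_class_only: bool = True,
             eigs: dict[str, EigenStructure] | None = None) -> list[str]:
    """The k nearest pool members to the query by EROS distance.

    The pool excludes the query and, when ``same_class_only``, is restricted
    to the query's class.  Ties are broken by subject_id lexicographic order.
    Precomputed eigenstructures may be supplied to avoid repeated
    decompositions.
    """
    pheno = dataset.phenotypes
    if query_id not in pheno.subject_ids:
        raise KeyError(f"unknown subject {query_id}")
    query_label = pheno.label_of(query_id)
    pool = [s for s in pheno.subject_ids if s != query_id]
    if same_class_only:
        pool = [s for s in pool if pheno.label_of(s) == query_label]
    if len(pool) < k:
        raise ConfigError(f"pool of {len(pool)} eligible subjects is "
                          f"smaller than k={k}")
    if eigs is None:
        eigs = {s: covariance_eigen(dataset.series[s])
                for s in pool + [query_id]}
    q = eigs[query_id]
    ranked = sorted(pool, key=lambda s: (eros_distance(q, eigs[s], w), s))
    return ranked[:k]


def interpolate(x: np.ndarray, x_neighbor: np.ndarray,
                phi: float) -> np.ndarray:
    """Convex combination x + phi * (x_neighbor - x)."""
    x = np.asarray(x, dtype=np.float64)
    x_neighbor = np.asarray(x_neighbor, dtype=np.float64)
    if x.shape != x_neighbor.shape:
        raise DimensionError("feature vectors differ in length")
    if not 0.0 <= phi <= 1.0:
        raise ConfigError(f"phi must be in [0,1], got {phi}")
    return x + phi * (x_neighbor - x)


def synthetic_id(source_id: str, round_index: int) -> str:
    return f"{source_id}__aug{round_index}"


def is_synthetic(subject_id: str) -> bool:
    return "__aug" in subject_id


def augment(dataset: Dataset, config: AugmentationConfig) -> Dataset:
    """Grow the cohort to gamma x its size with interpolated feature vectors.

    Per augmentation round, one synthetic sample is created for every
    original subject: its k nearest same-class neighbours (EROS distance on
    the raw time series) are found, one is drawn uniformly, and the feature
    vectors are interpolated with phi ~ Uniform(phi_range).  Synthetic
    subjects inherit the source's label and site and carry features only.
    gamma=1 returns the input unchanged.
    """
    if dataset.features is None:
        raise ConfigError("augment requires a dataset with features")
    missing = [s for s in dataset.phenotypes.subject_ids
               if s not in dataset.features]
    if missing:
        raise ConfigError(f"features missing for subjects {missing[:5]}")
    if config.gamma == 1:
        return dataset

    pheno = dataset.phenotypes
    for cls in (0, 1):
        pool = int(np.sum(pheno.labels == cls))
        if config.same_class_only and pool < config.k + 1:
            raise ConfigError(
                f"class {cls} has {pool} subjects; need >= k+1 = "
                f"{config.k + 1} for augmentation")

    rng = np.random.default_rng(config.seed)
    eigs = {s: covariance_eigen(dataset.series[s])
            for s in pheno.subject_ids}
    w = eros_weights(list(eigs.values()))
    neighbours = {
        s: knn_eros(s, dataset, w, config.k,
                    same_class_only=config.same_class_only, eigs=eigs)
        for s in pheno.subject_ids
    }

    new_ids = list(pheno.subject_ids)
    new_labels = list(pheno.labels)
    new_sites = list(pheno.site_ids)
    features = dict(dataset.features)
    lo, hi = config.phi_range
    for round_index in range(1, config.gamma):
        for sid in pheno.subject_ids:
            chosen = neighbours[sid][rng.integers(config.k)]
            phi = float(rng.uniform(lo, hi))
            new_vec = interpolate(features[sid],
                                  dataset.features[chosen], phi)
            syn = synthetic_id(sid, round_index)
            new_ids.append(syn)
            new_labels.append(pheno.label_of(sid))
            new_sites.append(pheno.site_of(sid))
            features[syn] = new_vec

    out_pheno = PhenotypeTable(tuple(new_ids),
                               np.array(new_labels, dtype=np.int64),
                               tuple(new_sites))
    out = Dataset(phenotypes=out_pheno, series=dict(dataset.series),
                  features=features)
    out.validate(allow_feature_only=True)
    return out
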