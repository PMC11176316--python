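"""Synthetic two-class cohorts of multivariate Gaussian time series.

Each class has its own ROI-ROI correlation matrix; the two matrices differ
by ``delta`` on a chosen set of ROI pairs.  Subjects are T i.i.d. draws from
a zero-mean multivariate normal with the class correlation (via Cholesky),
optionally shifted by per-site ROI mean offsets.  Because the draws are
i.i.d. in time, the empirical Pearson connectivity converges to the
generating correlation as T grows — which is exactly what makes the cohorts
useful for end-to-end testing of a correlation-based classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import Dataset, PhenotypeTable, RoiTimeSeries
from .errors import ConfigError

_PD_EPS = 1e-8


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects_per_class: int
    n_rois: int
    T: int
    effect_pairs: tuple[tuple[int, int], ...] = ()
    delta: float = 0.0
    base_rho: float = 0.0
    n_sites: int = 1
    site_shift_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_class < 1:
            raise ConfigError("n_subjects_per_class must be positive")
        if self.n_rois < 2:
            raise ConfigError("n_rois must be >= 2")
        if self.T < 3:
            raise ConfigError("T must be >= 3")
        if not 0.0 <= self.delta < 1.0:
            raise ConfigError("delta must be in [0, 1)")
        if not -1.0 < self.base_rho < 1.0:
            raise ConfigError("base_rho must be in (-1, 1)")
        if abs(self.base_rho) + self.delta >= 1.0:
            raise ConfigError("|base_rho| + delta must be < 1")
        if self.n_sites < 1:
            raise ConfigError("n_sites must be positive")
        if self.site_shift_sd < 0:
            raise ConfigError("site_shift_sd must be nonnegative")
        pairs = []
        for (i, j) in self.effect_pairs:
            if not (0 <= i < j < self.n_rois):
                raise ConfigError(f"effect pair ({i},{j}) must satisfy "
                                  f"0 <= i < j < n_rois")
            pairs.append((int(i), int(j)))
        if len(set(pairs)) != len(pairs):
            raise ConfigError("duplicate effect pairs")
        object.__setattr__(self, "effect_pairs", tuple(pairs))


def random_effect_pairs(n_rois: int, n_pairs: int,
                        seed: int) -> tuple[tuple[int, int], ...]:
    """Sample ``n_pairs`` distinct ROI pairs (i<j) uniformly."""
    all_pairs = [(i, j) for i in range(n_rois) for j in range(i + 1, n_rois)]
    if n_pairs > len(all_pairs):
        raise ConfigError(f"requested {n_pairs} pairs but only "
                          f"{len(all_pairs)} exist")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    return tuple(all_pairs[i] for i in sorted(idx))


def _nearest_pd_correlation(mat: np.ndarray) -> np.ndarray:
    """Eigenvalue clipping followed by rescaling back to unit diagonal."""
    vals, vecs = np.linalg.eigh(mat)
    vals = np.clip(vals, _PD_EPS, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    return (fixed + fixed.T) / 2.0


def make_class_correlation(config: SimulationConfig,
                           class_label: int) -> np.ndarray:
    """Correlation matrix for one class.

    Class 0 carries ``base_rho`` on every off-diagonal entry; class 1 adds
    ``delta`` on the effect pairs.  If the raw matrix is not positive
    definite it is re-projected by eigenvalue clipping (which may perturb
    the stated entries slightly); a matrix still non-PD afterwards raises.
    """
    if class_label not in (0, 1):
        raise ConfigError("class_label must be 0 or 1")
    n = config.n_rois
    mat = np.full((n, n), config.base_rho)
    np.fill_diagonal(mat, 1.0)
    if class_label == 1:
        for (i, j) in config.effect_pairs:
            mat[i, j] = mat[j, i] = config.base_rho + config.delta
    eigvals = np.linalg.eigvalsh(mat)
    if eigvals.min() <= 0:
        mat = _nearest_pd_correlation(mat)
        if np.linalg.eigvalsh(mat).min() <= 0:
            raise ConfigError(
                "correlation matrix not positive definite even after "
                "re-projection; reduce delta and/or base_rho")
    return mat


def simulate_cohort(config: SimulationConfig) -> Dataset:
    """Draw the full two-class cohort; deterministic given ``config.seed``.

    Subjects alternate class (patient/control interleaved) and are assigned
    to sites round-robin, so every site sees both classes whenever
    ``n_subjects_per_class >= n_sites``.
    """
    rng = np.random.default_rng(config.seed)
    chol = {c: np.linalg.cholesky(make_class_correlation(config, c))
            for c in (0, 1)}
    site_names = [f"site{k:02d}" for k in range(config.n_sites)]
    site_offsets = rng.normal(0.0, config.site_shift_sd,
                              size=(config.n_sites, config.n_rois)) \
        if config.site_shift_sd > 0 else np.zeros((config.n_sites,
                                                   config.n_rois))

    ids: list[str] = []
    labels: list[int] = []
    sites: list[str] = []
    series: dict[str, RoiTimeSeries] = {}
    m = config.n_subjects_per_class
    for idx in range(2 * m):
        label = idx % 2          # interleave patient/control
        site_idx = (idx // 2) % config.n_sites   # same site for each pair,
        # so sites never confound class even when n_sites divides 2
        sid = f"sub{idx:04d}"
        z = rng.standard_normal((config.T, config.n_rois))
        values = z @ chol[label].T + site_offsets[site_idx]
        ids.append(sid)
        labels.append(label)
        sites.append(site_names[site_idx])
        series[sid] = RoiTimeSeries(sid, values)

    pheno = PhenotypeTable(tuple(ids), np.array(labels, dtype=np.int64),
                           tuple(sites))
    ds = Dataset(phenotypes=pheno, series=series)
    ds.validate()
    return ds
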