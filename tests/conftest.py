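import numpy as np
import pytest

from asd_swnet import (SimulationConfig, compute_features, simulate_cohort)
from asd_swnet.synthetic_cohort import random_effect_pairs


@pytest.fixture(scope="session")
def small_cohort():
    """8 subjects/class, 6 ROIs, T=60, moderate class signal, 2 sites."""
    pairs = random_effect_pairs(6, 4, seed=11)
    cfg = SimulationConfig(n_subjects_per_class=8, n_rois=6, T=60,
                           effect_pairs=pairs, delta=0.5, base_rho=0.1,
                           n_sites=2, seed=42)
    return compute_features(simulate_cohort(cfg))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_orthonormal(n: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-ish orthonormal matrix via QR of a Gaussian draw."""
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def random_eigenstructure(n: int, rng: np.random.Generator, subject_id="s"):
    from asd_swnet import EigenStructure
    vals = np.sort(rng.uniform(0.1, 5.0, size=n))[::-1]
    return EigenStructure(subject_id, random_orthonormal(n, rng), vals)
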