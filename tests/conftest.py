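import numpy as np
import pytest

from epidiv.band_data import BandMatrix, Grouping, SampleMeta
from epidiv.simulate import SimConfig, simulate_band_matrix


def make_samples(spec):
    """spec: list of (group, n, gamma_dose, agent, conc) tuples."""
    out = []
    for group, n, dose, agent, conc in spec:
        for i in range(n):
            out.append(SampleMeta(f"{group}_{i}", group, dose, agent, conc))
    return out


def random_matrix(rng, n_samples=6, n_loci=8, marker="MSAP", p_missing=0.0,
                  groups=None):
    if groups is None:
        groups = [("A", n_samples // 2, 0.0, "none", 0.0),
                  ("B", n_samples - n_samples // 2, 100.0, "none", 0.0)]
    samples = make_samples(groups)
    n = len(samples)
    calls_m = rng.integers(0, 2, size=(n, n_loci), dtype=np.int8)
    calls_h = rng.integers(0, 2, size=(n, n_loci), dtype=np.int8)
    missing = rng.random((n, n_loci)) < p_missing
    loci = [f"L{j}" for j in range(n_loci)]
    return BandMatrix(marker, loci, samples, calls_m, calls_h, missing)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_matrix(rng):
    return random_matrix(rng)


@pytest.fixture
def sim_default():
    cfg = SimConfig(seed=11)
    bm, truth = simulate_band_matrix(cfg, "MSAP")
    return cfg, bm, truth


@pytest.fixture
def class_grouping():
    def _make(matrix):
        return Grouping.from_samples(matrix.samples, "treatment_class")
    return _make
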