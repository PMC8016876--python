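import numpy as np
import pandas as pd
import pytest

from txaging.normalize import CountMatrix
from txaging.simulate import SimConfig, simulate_counts, simulate_isoforms


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated cohort shared across read-only tests."""
    cfg = SimConfig(
        n_genes=150,
        n_samples=53,
        frac_age_assoc=0.1,
        beta_age_effect=0.03,
        frac_structural_zero_genes=0.1,
        seed=11,
    )
    cm, samples, truth = simulate_counts(cfg)
    return cfg, cm, samples, truth


@pytest.fixture(scope="session")
def isoform_dataset():
    """Counts plus an isoform layer with strong usage drift."""
    cfg = SimConfig(
        n_genes=80,
        n_samples=53,
        frac_age_assoc=0.0,
        frac_structural_zero_genes=0.0,
        n_transcripts_per_gene=(2, 3),
        frac_dtu_genes=0.3,
        usage_drift_magnitude=0.5,
        seed=23,
    )
    cm, samples, truth = simulate_counts(cfg)
    iso, tx2gene = simulate_isoforms(cm, cfg, truth, samples)
    return cfg, cm, samples, truth, iso, tx2gene


@pytest.fixture
def tiny_counts():
    """A hand-sized count matrix with known library sizes."""
    counts = pd.DataFrame(
        {
            "s1": [10, 7, 0, 0],
            "s2": [20, 0, 0, 5],
            "s3": [0, 3, 0, 1],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    lib = pd.Series({"s1": 80_000_000, "s2": 80_000_000, "s3": 80_000_000})
    return CountMatrix(counts=counts, library_size=lib)


@pytest.fixture
def ages53():
    rng = np.random.default_rng(5)
    return rng.uniform(22, 83, 53)


@pytest.fixture
def sexes53():
    return (np.arange(53) % 2).astype(float)
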