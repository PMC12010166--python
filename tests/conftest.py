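import numpy as np
import pandas as pd
import pytest

from psgsurv.simulate import SimulationConfig, luad_config, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-sample LUAD-style cohort, shared across tests (read-only)."""
    cfg = luad_config(seed=11, n_samples=80, n_background_genes=60)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def female_cohort():
    """A 271-sample all-female cohort with the causal panel effect."""
    cfg = luad_config(seed=7, n_samples=271, female_fraction=1.0,
                      n_background_genes=100)
    return simulate_cohort(cfg)


@pytest.fixture
def tiny_expression():
    genes = ["G1", "G2", "G3"]
    samples = ["s1", "s2", "s3", "s4"]
    values = np.array([
        [0.0, 0.1, 5.0, 0.0],
        [0.0, 0.0, 1.0, 0.0],
        [2.0, 0.0, 0.0, 0.0],
    ])
    return pd.DataFrame(values, index=genes, columns=samples)


def make_clinical(n, rng, female_fraction=0.5):
    sex = np.where(rng.random(n) < female_fraction, "female", "male")
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "sex": sex,
        "age": rng.normal(65, 8, n).round(1),
        "race": ["White"] * n,
        "stage": ["I"] * n,
        "time": rng.exponential(30, n).round(2),
        "event": rng.integers(0, 2, n),
    })
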