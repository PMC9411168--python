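import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from kinoflow import SimConfig

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

PLANTED = frozenset({"K001", "K002", "K003", "K004", "K005"})


@pytest.fixture
def small_null_config():
    """Small null experiment: no planted effect, modest grid."""
    return SimConfig(
        n_peptides=36, n_kinases=8, peptides_per_kinase=(3, 6), effect_size=0.0, seed=11
    )


@pytest.fixture
def planted_config():
    """Study-scale experiment with five planted kinases at 1.5 pooled SD."""
    return SimConfig(planted_kinases=PLANTED, effect_size=1.5, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_values(rng):
    """Random QC-passing value matrix, 12 peptides x 4v4 samples."""
    peptides = [f"P{i:03d}" for i in range(1, 13)]
    samples = [f"G1S{i}" for i in range(1, 5)] + [f"G2S{i}" for i in range(1, 5)]
    values = pd.DataFrame(rng.normal(3, 1, (12, 8)), index=peptides, columns=samples)
    groups = {s: (1 if s.startswith("G1") else 2) for s in samples}
    return values, groups
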