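import numpy as np
import pytest

from celest.core_io import ExpressionMatrix, SampleAnnotation
from celest.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Four balanced classes, three batches, planted biomarkers and
    two-class CE-DEGs; shared across read-only tests."""
    cfg = SimulationConfig(
        n_genes=400,
        class_sizes={"A": 30, "B": 30, "C": 30, "CTR": 30},
        n_batches=3,
        n_ce_degs=10,
        n_biomarkers_per_class=4,
        effect_size=1.5,
        noise_sd=0.5,
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_matrix():
    return ExpressionMatrix(
        np.array([[1.0, 2.0], [3.0, 4.0]]), ["gA", "gB"], ["s1", "s2"]
    )
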