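import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from texpress import CountMatrix, FeatureAnnotation, SimConfig, simulate_counts

settings.register_profile(
    "texpress",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("texpress")


@pytest.fixture
def tiny_annotation():
    return [
        FeatureAnnotation("gene1", "gene"),
        FeatureAnnotation("gene2", "gene"),
        FeatureAnnotation("L1MB4", "TE", "L1MB4", "L1", "LINE"),
        FeatureAnnotation("AluY", "TE", "AluY", "Alu", "SINE"),
        FeatureAnnotation("LTR5_HS", "TE", "LTR5_HS", "ERVK", "LTR"),
        FeatureAnnotation("Charlie1", "TE", "Charlie1", "hAT", "DNA"),
    ]


@pytest.fixture
def small_study():
    """A small simulated study with a broad TE shift, shared across tests."""
    cfg = SimConfig(
        n_genes=300,
        n_tes_per_class={"LINE": 30, "SINE": 20, "LTR": 20, "DNA": 10},
        n_samples_per_group=8,
        seed=11,
    )
    return simulate_counts(cfg)


def make_matrix(values, prefix="f", normalized=False):
    values = np.asarray(values, dtype=float)
    return CountMatrix(
        values,
        tuple(f"{prefix}{i}" for i in range(values.shape[0])),
        tuple(f"s{j}" for j in range(values.shape[1])),
        normalized=normalized,
    )
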