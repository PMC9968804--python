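import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mir3d import ExpressionMatrix, SimConfig, simulate_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_cfg() -> SimConfig:
    """Desk-scale study conditions shrunk further for fast unit tests."""
    return SimConfig(
        n_chrom=2,
        bins_per_chrom=12,
        n_domains=4,
        n_mirna=60,
        frac_multimapped=0.1,
        n_case=15,
        n_control=15,
        n_informative=8,
        n_informative_clusters=2,
        effect_size=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cfg):
    return simulate_dataset(tiny_cfg)


def make_matrix(values, labels, mirna_ids=None, sample_ids=None) -> ExpressionMatrix:
    """Hand-build a small expression matrix for arithmetic fixtures."""
    values = np.asarray(values, dtype=float)
    n_mir, n_s = values.shape
    mirna_ids = mirna_ids or [f"m{i}" for i in range(n_mir)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_s)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=mirna_ids, columns=sample_ids),
        pd.Series(labels, index=sample_ids),
    )
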