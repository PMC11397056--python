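import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_counts():
    """4 features x 3 samples with known totals."""
    return pd.DataFrame(
        {
            "s1": [30, 25, 0, 10],
            "s2": [11, 25, 0, 10],
            "s3": [10, 0, 0, 10],
        },
        index=pd.Index(["fA", "fB", "fC", "fD"], name="feature_id"),
    )


def random_counts(rng, n_features=50, n_samples=6, mean=100.0):
    return pd.DataFrame(
        rng.poisson(mean, size=(n_features, n_samples)),
        index=pd.Index([f"f{i}" for i in range(n_features)], name="feature_id"),
        columns=[f"s{j}" for j in range(n_samples)],
    )
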