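import numpy as np
import pandas as pd
import pytest


def make_pairs(beta_x, se_x, beta_y, se_y, **extra):
    """Build a harmonized-pair frame from aligned effect arrays."""
    beta_x = np.atleast_1d(np.asarray(beta_x, dtype=float))
    n = len(beta_x)

    def expand(v):
        arr = np.asarray(v, dtype=float)
        return np.full(n, arr) if arr.ndim == 0 else arr

    df = pd.DataFrame({
        "rsid": [f"rs{i + 1}" for i in range(n)],
        "chrom": "1",
        "pos": 1_000_000 + 5_000 * np.arange(n),
        "effect_allele": "A",
        "other_allele": "G",
        "beta_x": beta_x,
        "se_x": expand(se_x),
        "beta_y": expand(beta_y),
        "se_y": expand(se_y),
        "eaf": 0.3,
        "flipped": False,
        "palindromic": False,
    })
    for k, v in extra.items():
        df[k] = v
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
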