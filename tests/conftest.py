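import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_condition_table(arms: dict[str, np.ndarray],
                         genotype: str = "Col-0") -> pd.DataFrame:
    """Long-format genotype/treatment/response table from arm arrays."""
    rows = []
    for treatment, values in arms.items():
        for i, v in enumerate(values):
            rows.append((genotype, treatment, "R1", f"p{i + 1}", float(v)))
    return pd.DataFrame(rows, columns=["genotype", "treatment", "replicate",
                                       "plant_id", "response"])


def make_feature_table(conditions: dict[str, np.ndarray]) -> pd.DataFrame:
    """Long-format screen table; each condition maps to a plants x features
    array, features named F01.."""
    rows = []
    for cond, mat in conditions.items():
        mat = np.atleast_2d(mat)
        for p in range(mat.shape[0]):
            for f in range(mat.shape[1]):
                rows.append((cond, "Col-0", "R1", f"p{p + 1}",
                             f"F{f + 1:02d}", float(mat[p, f])))
    return pd.DataFrame(rows, columns=["condition", "genotype", "replicate",
                                       "plant_id", "feature", "value"])
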