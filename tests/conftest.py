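import numpy as np
import pandas as pd
import pytest

from mmdiscover import CohortLabels, FeatureTable


def make_labels(n0: int, n1: int, contrast: str = "3+3 vs >=3+4") -> CohortLabels:
    ids = [f"S{i:03d}" for i in range(n0 + n1)]
    pats = ["3+3"] * n0 + ["3+4" if i % 2 == 0 else "4+3" for i in range(n1)]
    return CohortLabels(pd.Series(pats, index=ids), contrast)


def make_table(values: np.ndarray, modality: str = "miRNA",
               feature_prefix: str = "f") -> FeatureTable:
    n, p = values.shape
    ids = [f"S{i:03d}" for i in range(n)]
    cols = [f"{feature_prefix}{j}" for j in range(p)]
    return FeatureTable(pd.DataFrame(values, index=ids, columns=cols), modality)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
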