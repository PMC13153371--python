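import numpy as np
import pandas as pd
import pytest

from panquant.core_io import AbundanceMatrix, CohortLabel, ProteinAnnotation
from panquant.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def toy_matrix() -> AbundanceMatrix:
    """3 proteins x 4 samples, two cohorts, one missing cell."""
    values = pd.DataFrame(
        {
            "T1": [20.0, 18.0, np.nan],
            "T2": [21.0, 17.5, 15.0],
            "N1": [19.5, 18.2, 14.8],
            "N2": [20.5, 17.9, 15.2],
        },
        index=["P1", "P2", "P3"],
    )
    cohorts = {
        "T1": CohortLabel("LUAD", "tumor"),
        "T2": CohortLabel("LUAD", "tumor"),
        "N1": CohortLabel("LUAD", "normal"),
        "N2": CohortLabel("LUAD", "normal"),
    }
    return AbundanceMatrix(values, cohorts)


@pytest.fixture
def toy_annotation() -> ProteinAnnotation:
    return ProteinAnnotation(pd.Series({"P1": 4, "P2": 1, "P3": 10}))


@pytest.fixture(scope="session")
def default_dataset():
    """One medium synthetic dataset shared by read-only tests."""
    cfg = SyntheticConfig(n_proteins=800, seed=123, indications=("BRCA", "LUAD", "COAD"))
    return generate_dataset(cfg)
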