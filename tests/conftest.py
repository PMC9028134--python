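import numpy as np
import pandas as pd
import pytest

from venomdelta.compose import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """Four samples (two per species), six transcripts, TPM-like scale."""
    vals = pd.DataFrame(
        {
            "cot_1": [100.0, 200.0, 50.0, 400.0, 150.0, 100.0],
            "cot_2": [110.0, 190.0, 55.0, 420.0, 140.0, 85.0],
            "fon_1": [90.0, 210.0, 300.0, 380.0, 160.0, 60.0],
            "fon_2": [105.0, 205.0, 310.0, 390.0, 150.0, 40.0],
        },
        index=[f"t{i}" for i in range(6)],
    )
    species = pd.Series({"cot_1": "cotiara", "cot_2": "cotiara",
                         "fon_1": "fonsecai", "fon_2": "fonsecai"})
    classes = pd.Series(["PLA2", "SVMP", "nontoxin", "nontoxin",
                         "nontoxin", "nontoxin"], index=vals.index)
    return ExpressionMatrix(vals, species, classes)
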