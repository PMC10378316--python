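import warnings

import numpy as np
import pandas as pd
import pytest

from mirepos.containers import ExpressionMatrix
from mirepos.synthdata import SynthConfig


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Generator/statistics warnings are part of normal operation here."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def small_cfg():
    """Scaled-down study conditions used for fast module tests."""
    return SynthConfig(
        seed=7,
        n_tumor=10,
        n_normal=10,
        n_matched_pairs=4,
        n_features=80,
        n_planted_de=12,
        n_blood_concordant=4,
        n_low_probes=10,
        n_lines=12,
        n_drugs=4,
        n_subjects=120,
        n_perturbagens=12,
    )


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(11)
    values = pd.DataFrame(
        rng.normal(8.0, 1.0, size=(6, 4)),
        index=[f"feat{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(4)],
    )
    values.iloc[1, 2] = np.nan
    return ExpressionMatrix(values)
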