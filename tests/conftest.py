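import warnings

import numpy as np
import pandas as pd
import pytest

from bsdrisk.cohort import CohortTable, default_manifest
from bsdrisk.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    """Degenerate-column warnings from fold-level refits are expected
    noise in small simulated cohorts."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="dropping zero-variance")
        warnings.filterwarnings("ignore", message="reducing folds")
        warnings.filterwarnings("ignore", message=".*constant among complete cases.*")
        yield


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded cohort at the study's default conditions
    (n=105, ~18 events, 60-month horizon, 10% missingness)."""
    cohort, truth = generate_cohort(GeneratorConfig(seed=20))
    return cohort, truth


@pytest.fixture(scope="session")
def complete_cohort():
    """Default-size cohort without missingness (for stages that need a
    complete design)."""
    cohort, truth = generate_cohort(GeneratorConfig(seed=21, missing_fraction=0.0))
    return cohort, truth


def tiny_cohort_frame():
    """A 3-subject hand-written cohort covering one missing severity."""
    manifest = {"age_years": "continuous", "sev_M3": "ordinal",
                "prev_M3": "binary"}
    df = pd.DataFrame({
        "subject_id": ["a", "b", "c"],
        "time_months": [12.0, 24.0, 36.0],
        "event": [1, 0, 0],
        "age_years": [14.0, 15.5, 17.0],
        "sev_M3": [3.0, np.nan, 0.0],
        "prev_M3": [1.0, 0.0, 0.0],
    })
    return df, manifest


@pytest.fixture
def tiny_cohort():
    df, manifest = tiny_cohort_frame()
    return CohortTable(df, manifest)
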