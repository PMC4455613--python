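"""Shared fixtures: small simulated cohorts, preprocessed once per session."""

import numpy as np
import pytest

from irscreen import CohortConfig, preprocess_pipeline, simulate_cohort


def preprocess_cohort(config: CohortConfig):
    """Simulate and preprocess a cohort; returns (datasets, records)."""
    spectra, records = simulate_cohort(config)
    result = preprocess_pipeline(spectra, {r.subject_id: r.group for r in records})
    return result.datasets, records


@pytest.fixture(scope="session")
def planted_cohort():
    """Default study design with the calibration malignancy effects planted."""
    return preprocess_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def null_cohort():
    """Same design with no class effects: every class difference is noise."""
    return preprocess_cohort(
        CohortConfig(seed=2, effects=[], clinical_effects={})
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
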