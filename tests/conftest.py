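"""Shared fixtures: the default phantom cohort and its measurement sweep.

The cohort and the measurement sweep are expensive (distance transforms on a
96^3 grid for every patient x hemisphere x tract x threshold), so they are
built once per session and shared by the module tests and the acceptance
suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from tractgap.config import RunConfig
from tractgap.pipeline import measure_cohort
from tractgap.synthetic_data import generate_cohort, make_grid


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()  # 10 patients, 96^3 grid at 2 mm, seed 0


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def cohort_measurements(default_cohort, default_config):
    """(sensitivity long-form table, measurement records, threshold selections)."""
    return measure_cohort(default_cohort, default_config)


@pytest.fixture(scope="session")
def contact_positions(default_cohort):
    """(patient_id, hemisphere, contact_index) -> world position array."""
    return {
        (c.patient_id, c.hemisphere, c.contact_index): c.position.to_array()
        for p in default_cohort.patients
        for c in p.contacts
    }


@pytest.fixture()
def small_grid():
    return make_grid(shape=(20, 20, 20), spacing=(2.0, 2.0, 2.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
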