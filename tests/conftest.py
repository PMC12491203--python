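"""Shared fixtures: small synthetic cohorts and extracted feature matrices.

Cohort generation and feature extraction are the slowest fixtures, so the
default cohort (seed 1) and its feature matrix are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaitfusion.config import RunConfig
from gaitfusion.pipeline import run_extract
from gaitfusion.synthetic import default_spec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    cohort, manifest = generate_cohort(default_spec(seed=1))
    return cohort, manifest


@pytest.fixture(scope="session")
def default_matrix(default_cohort):
    cohort, _ = default_cohort
    matrix, rejects = run_extract(cohort, RunConfig(seed=1))
    assert not rejects
    return matrix


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
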