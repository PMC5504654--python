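"""Shared fixtures: small deterministic matrices and cohorts."""

import numpy as np
import pytest

from syndel import (
    CohortSpec,
    MatrixSpec,
    generate_cohort,
    generate_matrix,
    load_registry,
    questionnaire,
)


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def male_question_ids():
    return [q.id for q in questionnaire("male")]


@pytest.fixture(scope="session")
def matrix(registry):
    """A full-size synthetic original matrix (177 questions)."""
    return generate_matrix(MatrixSpec(seed=11), registry)


@pytest.fixture(scope="session")
def small_matrix(registry):
    """A 20-question matrix for fast per-record tests."""
    return generate_matrix(MatrixSpec(n_questions=20, links_per_question=(2, 5), seed=7), registry)


@pytest.fixture(scope="session")
def cohort(male_question_ids):
    """30 records over the full male questionnaire."""
    return generate_cohort(CohortSpec(n_records=30, seed=13), male_question_ids)


@pytest.fixture(scope="session")
def small_cohort():
    """10 records over a 20-question instrument."""
    return generate_cohort(CohortSpec(n_records=10, seed=17), list(range(1, 21)))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
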