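"""Shared fixtures: one mid-size phantom case and its lateral-beam views.

Session-scoped because phantom generation and DRR computation dominate
unit-test runtime; tests must not mutate these objects.
"""

from __future__ import annotations

import numpy as np
import pytest

from autowbrt import (
    PhantomSpec,
    compute_drr,
    generate_phantom,
    project_contour_bev,
)
from autowbrt.field_builder import compute_vertebral_landmarks
from autowbrt.segmentation import examples_from_cases, train_model


@pytest.fixture(scope="session")
def case():
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def beam_left(case):
    return case.beam("left-lateral")


@pytest.fixture(scope="session")
def body_left(case, beam_left):
    return project_contour_bev(case.structures["body"], beam_left)


@pytest.fixture(scope="session")
def drr_left(case, beam_left):
    return compute_drr(case.ct, beam_left, case.bev_grid)


@pytest.fixture(scope="session")
def landmarks(case):
    return compute_vertebral_landmarks(case.structures, case.ct)


@pytest.fixture(scope="session")
def reference_left(case):
    return case.reference_apertures[("left-lateral", case.clinical_extent)]


@pytest.fixture(scope="session")
def tiny_model(case):
    """A model trained on the single fixture case — mechanics, not accuracy."""
    examples = examples_from_cases([case])
    return train_model(examples, examples, config={"epochs": 15}, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
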