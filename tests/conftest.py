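"""Shared fixtures: small synthetic biopsies generated once per session."""

import numpy as np
import pytest

from milscore.synthetic import SyntheticSpec, generate_biopsy


@pytest.fixture(scope="session")
def clean_biopsy():
    """A 512-px artefact-free biopsy with neutrophils in the epithelium."""
    spec = SyntheticSpec(
        image_size=512, subgrade_severities={"PolysEP": 2, "MonosLP": 1}, seed=11
    )
    img, truth = generate_biopsy(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def artefact_biopsy():
    """A 512-px biopsy carrying all four planted artefact types."""
    spec = SyntheticSpec(
        image_size=512,
        subgrade_severities={"PolysEP": 1},
        artefact_types=("blank", "blur", "shear_streak", "fold"),
        artefact_fraction=0.3,
        seed=23,
    )
    img, truth = generate_biopsy(spec)
    return spec, img, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
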