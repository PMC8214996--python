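"""Shared fixtures: the default synthetic study, computed once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pastage.augment import augment_set
from pastage.mrmr import build_feature_matrix, mrmr_rank
from pastage.preprocess import preprocess_set
from pastage.synth import StudyDesign, default_templates, generate_dataset
from pastage.wpd import extract_aa2_features

SESSION_SEED = 11


@pytest.fixture(scope="session")
def default_design() -> StudyDesign:
    return StudyDesign()


@pytest.fixture(scope="session")
def small_design() -> StudyDesign:
    """Reduced factorial layout (40 originals) for fast end-to-end checks."""
    return StudyDesign(
        n_tissues_per_group=2, n_positions_per_tissue=2, n_replicates_per_position=2
    )


@pytest.fixture(scope="session")
def original_spectra(default_design):
    return generate_dataset(default_design, default_templates(default_design), SESSION_SEED)


@pytest.fixture(scope="session")
def roi_spectra(original_spectra):
    return preprocess_set(original_spectra)


@pytest.fixture(scope="session")
def augmented_spectra(roi_spectra):
    return augment_set(roi_spectra)


@pytest.fixture(scope="session")
def feature_table(augmented_spectra) -> pd.DataFrame:
    return extract_aa2_features(augmented_spectra)


@pytest.fixture(scope="session")
def ranking(feature_table):
    return mrmr_rank(feature_table, k=10)


@pytest.fixture(scope="session")
def feature_matrix(feature_table, ranking) -> pd.DataFrame:
    return build_feature_matrix(feature_table, ranking, 10)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(SESSION_SEED)
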