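import logging

import numpy as np
import pytest

from conntda import (
    generate_dataset,
    impute_pds,
    make_parcellation,
    simulate_cohort,
    simulate_features,
)

logging.getLogger("conntda").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_distance(rng, n, hi=2.0):
    a = rng.uniform(0.05, hi, size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a


@pytest.fixture(scope="session")
def cohort_and_features():
    """Full-scale cohort with the default peaked pubertal effect,
    QC-filtered and PDS-imputed, plus its feature table."""
    cohort, gt = simulate_cohort(seed=11)
    cohort = impute_pds(cohort)
    cohort = cohort[cohort["qc_pass"]].reset_index(drop=True)
    features = simulate_features(cohort, gt)
    return cohort, features, gt


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small on-disk dataset: 10 subjects, 45 ROIs, 150 volumes."""
    path = tmp_path_factory.mktemp("ds") / "dataset"
    return generate_dataset(path, n_subjects=10, n_rois=45, t=150, seed=5)


@pytest.fixture(scope="session")
def parcellation264():
    return make_parcellation(264)
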