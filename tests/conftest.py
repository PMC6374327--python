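import numpy as np
import pytest

from hsrc import (
    Grid,
    SyntheticSpec,
    assemble_feature_matrix,
    build_pyramid,
    downsample_binary,
    generate_cohort,
    make_folds,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small strong-effect cohort on a 16^3 grid (fast fixture)."""
    spec = SyntheticSpec(
        n_per_group=30, shape=(16, 16, 16), cluster_radius=2.0, seed=7
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return assemble_feature_matrix(small_cohort.volumes, small_cohort.subject_ids)


@pytest.fixture(scope="session")
def small_folds(small_cohort):
    n = len(small_cohort.volumes)
    return make_folds(n, 5, small_cohort.labels, seed=3)


@pytest.fixture(scope="session")
def level_setup(small_cohort):
    """Two-level matrices + pyramid for cascade tests."""
    ids = small_cohort.subject_ids
    fine = small_cohort.volumes
    coarse = [downsample_binary(v, 2) for v in fine]
    mats = [
        assemble_feature_matrix(fine, ids),
        assemble_feature_matrix(coarse, ids),
    ]
    pyramid = build_pyramid(fine[0].grid, 2)
    return mats, pyramid


@pytest.fixture
def identity_grid():
    return Grid(shape=(6, 5, 4), affine=np.eye(4))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
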