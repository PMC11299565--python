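import pytest

from neuromontage.stitch import default_layout, stitch_volume
from neuromontage.synthetic import CohortConfig, generate_atlas, generate_cohort


@pytest.fixture(scope="session")
def atlas20():
    """20-region atlas on the default 64³ grid."""
    return generate_atlas(20, (64, 64, 64), seed=3)


@pytest.fixture(scope="session")
def atlas_small():
    return generate_atlas(6, (32, 32, 32), seed=1)


@pytest.fixture(scope="session")
def small_cohort(atlas20):
    """Ten rendered subjects for image-path tests."""
    config = CohortConfig(n_subjects=10, seed=11)
    subjects, manifest = generate_cohort(atlas20, config)
    return subjects, manifest, config


@pytest.fixture(scope="session")
def geometry_cohort(atlas20):
    """Two thousand geometry-only subjects for distributional checks."""
    config = CohortConfig(n_subjects=2000, seed=5)
    subjects, manifest = generate_cohort(atlas20, config, render=False)
    return subjects, manifest, config


@pytest.fixture(scope="session")
def stitched_pair(atlas20, small_cohort):
    subjects, _, _ = small_cohort
    layout = default_layout(atlas20.label_volume.shape)
    imgs = [stitch_volume(s.volume, layout, s.subject_id) for s in subjects[:2]]
    return layout, imgs
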