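import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom_spec():
    """Seconds-scale phantom: ~200 bulk voxels per muscle on a 24x24x12 grid."""
    from gmaxff.synthetic import PhantomSpec

    def make(**overrides):
        defaults = dict(
            shape=(24, 24, 12),
            semi_axes_vox=(4.0, 4.0, 3.0),
            lt_slice=2,
            asis_slice=9,
            fat_shell=False,
        )
        defaults.update(overrides)
        return PhantomSpec(**defaults)

    return make


@pytest.fixture
def subject_metadata():
    return {
        "subject_id": "S001",
        "sex": "male",
        "weight_kg": 80.0,
        "height_cm": 180.0,
        "age_years": 30.0,
        "group": "High",
        "activity_hours_per_week": 9.0,
    }
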