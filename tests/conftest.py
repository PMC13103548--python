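import numpy as np
import pytest

from mdefusion.synthetic import ClassEffect, SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """4 + 4 subjects, 16-channel, 20 s at 128 Hz, strong alpha effect."""
    spec = SyntheticSpec(n_subjects_per_group=4, duration_s=20.0, fs=128.0,
                         montage_name="std16",
                         class_effect=ClassEffect(band="alpha", power_ratio=3.0,
                                                  corr_shift=0.2),
                         noise_sd=1.0, seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def edf_dir(small_cohort, tmp_path_factory):
    from mdefusion.synthetic import write_fixture_edf
    d = tmp_path_factory.mktemp("edf")
    write_fixture_edf(small_cohort, d)
    return d


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
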