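import numpy as np
import pytest

from radpt.features import BatteryConfig
from radpt.preprocess import PreprocessConfig
from radpt.simdata import PhantomConfig, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_study():
    """One preprocessed default-resolution phantom with a clear effect."""
    from radpt.preprocess import preprocess_study

    cfg = PhantomConfig(n_patients=1, seed=7, it_effect=1.0, pt_effect=1.0,
                        n_slices=(3, 3))
    return preprocess_study(generate_study(cfg, 0))


def fast_phantom(**overrides) -> PhantomConfig:
    """Coarse (1 mm) phantom used by simulation-heavy tests to stay in budget."""
    kw = dict(
        image_size=56,
        pixel_spacing=1.0,
        n_slices=(3, 3),
        lesion_radius_mm=(2.5, 3.5),
        two_lesion_prob=0.1,
        correlation_length_mm=1.2,
    )
    kw.update(overrides)
    return PhantomConfig(**kw)


def fast_preprocess(**overrides) -> PreprocessConfig:
    kw = dict(target_pixel_spacing=1.0, target_slice_thickness=3.0)
    kw.update(overrides)
    return PreprocessConfig(**kw)


def fast_battery(**overrides) -> BatteryConfig:
    """Reduced battery (same families, fewer kernels) for simulation tests."""
    kw = dict(
        gabor_wavelengths=(3.0, 5.0),
        gabor_n_orientations=4,
        haralick_windows=(3, 5),
        n_levels=8,
        allow_any_bank=True,
    )
    kw.update(overrides)
    return BatteryConfig(**kw)
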