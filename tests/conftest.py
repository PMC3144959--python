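import numpy as np
import pytest

from cardiostain import PhantomParams, generate_stack

# Published per-heart aggregates (three reporter-positive hearts) used as
# inputs by the aggregation tests.
LEFT_MEANS = [7031.0, 22806.0, 37763.0]
RIGHT_MEANS = [965.0, 1827.0, 2521.0]
LEFT_PCTS = [87.5, 92.2, 87.9]
RIGHT_PCTS = [12.5, 7.8, 12.1]


def small_params(**overrides) -> PhantomParams:
    """Desk-scale phantom parameters shared across the suite."""
    defaults = dict(
        n_slices=3,
        frame_height=240,
        frame_width=180,
        left_fraction=0.9,
        noise_sd=4.0,
        n_stain_patches=10,
        patch_radius_range=(4.0, 6.0),
        seed=1,
    )
    defaults.update(overrides)
    return PhantomParams(**defaults)


@pytest.fixture(scope="session")
def clean_stack():
    """Noise-free, jitter-free 3-slice stack with truth."""
    return generate_stack(small_params(noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_stack():
    """Noisy (sd=8) jitter-free stack."""
    return generate_stack(small_params(noise_sd=8.0, seed=2))


@pytest.fixture(scope="session")
def jittered_stack():
    """Stack with recorded rigid misalignments."""
    return generate_stack(
        small_params(n_slices=5, jitter_translation_max=8.0,
                     jitter_rotation_max=4.0, seed=3)
    )
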