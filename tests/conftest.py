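import numpy as np
import pytest

from vetbrain import ImageVolume, PhantomSpec
from vetbrain.phantom import make_reference, make_study


def small_spec(**overrides) -> PhantomSpec:
    """A reduced head phantom for fast unit tests (full-size studies are
    exercised in the acceptance suite)."""
    base = dict(
        seed=0,
        head_axes_mm=(30.0, 42.0, 32.0),
        brain_axes_mm=(18.0, 26.0, 16.0),
        skull_thickness_mm=2.5,
        noise_sd=0.0,
        margin_mm=5.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, bias-free small phantom: (spec, reference, truth)."""
    spec = small_spec(seed=11)
    ref, truth = make_reference(spec)
    return spec, ref, truth


@pytest.fixture(scope="session")
def clean_study():
    """Noise-free three-plane study: (spec, stacks, truth, metadata)."""
    spec = small_spec(seed=21)
    return (spec,) + make_study(spec)


@pytest.fixture(scope="session")
def noisy_study():
    """Mild-noise, mild-bias three-plane study matching the study conditions."""
    spec = small_spec(seed=31, noise_sd=0.01, bias_field=(0.1, 40.0))
    return (spec,) + make_study(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_volume(rng, shape=(12, 14, 16), affine=None) -> ImageVolume:
    aff = np.eye(4) if affine is None else affine
    return ImageVolume(rng.random(shape).astype(np.float64) + 0.1, aff)
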