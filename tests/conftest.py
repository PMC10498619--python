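import numpy as np
import pytest

from fabem import SliceClass, generate_corpus, generate_slice, random_spec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_corpus():
    """24 seeded 128×128 phantoms across all three layouts, gap rate 0.3."""
    records, manifest = generate_corpus(
        24, (0.5, 0.2, 0.3), gap_rate=0.3, seed=42, shape=(128, 128)
    )
    return records, manifest


@pytest.fixture(scope="session")
def closed_single_phantom():
    spec = random_spec(
        np.random.default_rng(7), layout=SliceClass.OTHER_LAYER, shape=(128, 128)
    )
    return generate_slice(spec)


@pytest.fixture(scope="session")
def multi_phantom():
    spec = random_spec(
        np.random.default_rng(8), layout=SliceClass.MULTI_REGION, shape=(128, 128)
    )
    return generate_slice(spec)


@pytest.fixture(scope="session")
def basis_phantom():
    spec = random_spec(
        np.random.default_rng(9), layout=SliceClass.BASIS_CRANII, shape=(128, 128)
    )
    return generate_slice(spec)


def random_mask(rng, shape=(32, 32), p=0.4):
    return rng.random(shape) < p


def blobby_mask(rng, shape=(32, 32)):
    """Random smooth-ish mask with nontrivial components."""
    from scipy import ndimage

    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    return noise > np.quantile(noise, 0.6)
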