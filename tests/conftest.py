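import warnings

import numpy as np
import pytest
from scipy.linalg import LinAlgWarning

from broadvol import (
    BLSConfig,
    ExtractorConfig,
    FeatureCache,
    PhantomSpec,
    PreprocessConfig,
    generate_dataset,
)

# The default ridge lam is tiny (the closed form takes lam -> 0), so the
# normal-equation matrix is near-singular by design; scipy flags it.
warnings.filterwarnings("ignore", category=LinAlgWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_extractor_cfg():
    """Reduced-width extractor: full 256/512 outputs, thin internals."""
    return ExtractorConfig(seed=0, stem_channels=16, m1_inner=16, m2_inner=16)


@pytest.fixture(scope="session")
def phantom_preprocess_cfg():
    return PreprocessConfig(crop_shape=(32, 32, 32))


@pytest.fixture(scope="session")
def phantom_dataset(tmp_path_factory):
    """40 AD + 40 NC phantoms at 32^3 voxels, effect 1.0, noise 0.05."""
    out = tmp_path_factory.mktemp("phantoms_e1")
    manifest = generate_dataset(
        40, PhantomSpec(effect_size=1.0, noise_sd=0.05, seed=0), out,
        classes=("AD", "NC"),
    )
    return manifest


@pytest.fixture(scope="session")
def null_phantom_dataset(tmp_path_factory):
    """Same conditions but effect_size 0: no class signal at all."""
    out = tmp_path_factory.mktemp("phantoms_e0")
    manifest = generate_dataset(
        40, PhantomSpec(effect_size=0.0, noise_sd=0.05, seed=0), out,
        classes=("AD", "NC"),
    )
    return manifest


@pytest.fixture(scope="session")
def shared_feature_cache():
    """One extractor-feature cache reused across end-to-end tests."""
    return FeatureCache()


@pytest.fixture
def gaussian_data():
    """2-class separable Gaussians: n=200, d=20, means +/-3 on axis 0."""
    g = np.random.default_rng(0)
    X = g.standard_normal((200, 20))
    X[:100, 0] += 3.0
    X[100:, 0] -= 3.0
    y = np.array(["A"] * 100 + ["B"] * 100)
    return X, y


@pytest.fixture
def default_classic_bls():
    return BLSConfig(mode="classic", seed=0)
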