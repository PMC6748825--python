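import numpy as np
import pytest

from finchsong.divergence import DivergenceConfig
from finchsong.synth import canonical_song_spec, generate_reference_corpus


@pytest.fixture(scope="session")
def canonical_spec():
    """Canonical 8.5 syl/s tutor blueprint with naturalistic gap jitter."""
    return canonical_song_spec()


@pytest.fixture(scope="session")
def rigid_spec():
    """Canonical blueprint with gap jitter off (deterministic timing)."""
    return canonical_song_spec(gap_rel_sd=0.0)


@pytest.fixture(scope="session")
def fast_sd_config():
    """Reduced-size SD configuration used for corpus-level tests."""
    return DivergenceConfig(
        basis_size=40, n_dims=8, k_range=(2, 10), n_init=2, mc_samples=20_000, seed=7
    )


@pytest.fixture(scope="session")
def reference_corpus(canonical_spec):
    """A 40-bout perfect-learner corpus shared across divergence tests."""
    return generate_reference_corpus(canonical_spec, 40, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
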