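import numpy as np
import pytest

from dermbench.synthetic import EmbeddingProfile, generate_embeddings


@pytest.fixture(scope="session")
def small_profile():
    """50 features, 5 informative, strong separation: the selector test bed."""
    return EmbeddingProfile(
        name="toy",
        dimension=50,
        n_informative=5,
        class_sizes=(40, 35, 30, 15),
        effect_size=5.0,
        noise_sd=1.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_table(small_profile):
    return generate_embeddings(small_profile)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
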