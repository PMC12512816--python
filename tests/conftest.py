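import numpy as np
import pytest

from ecglf.simulate import SimConfig, simulate_median_beats
from ecglf.vae import BetaVAE

#: reference training recipe: 200 training + 50 held-out subjects, beta 0.25
REFERENCE_SEED = 7


@pytest.fixture(scope="session")
def synthetic_beats():
    """250 noisy synthetic median beats with their true factors."""
    cfg = SimConfig(n_subjects=250, noise_sd=0.02, seed=REFERENCE_SEED)
    beats, factors = simulate_median_beats(cfg)
    return beats, factors


@pytest.fixture(scope="session")
def trained_vae(synthetic_beats):
    """Beta-VAE trained with the reference recipe; shared across tests.

    Returns (model, train_beats, val_beats).
    """
    beats, _ = synthetic_beats
    train = beats.subset(np.arange(200))
    val = beats.subset(np.arange(200, 250))
    model = BetaVAE(beta=0.25, epochs=60, seed=0).fit(train, X_val=val)
    return model, train, val


@pytest.fixture()
def tiny_vae_params():
    """Fast-training model configuration for logic (not quality) tests."""
    return dict(latent_dim=8, conv_spec=((4, 9), (8, 5)), epochs=2, batch_size=16, seed=0)
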