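"""Shared fixtures: small synthetic blocks generated at test time."""

import numpy as np
import pytest

import bistream as bs


@pytest.fixture(scope="session")
def small_synth() -> bs.SyntheticBlock:
    """8-site, 60-s block with a strong percept effect at two sites."""
    cfg = bs.SyntheticConfig(
        n_sites=8,
        seed=7,
        effect_sites=(0, 3),
        effect_amp=25.0,
        noise_sd=10.0,
        percept_mean_dur=(10.0, 12.0),
        artifact_rate=1.0,
    )
    stim = bs.TripletStimulus(n_triplets=100)  # 60 s
    return bs.simulate_block(cfg, stim)


@pytest.fixture(scope="session")
def small_epochs(small_synth) -> bs.LabeledEpochs:
    return bs.preprocess_block(small_synth.block, rt=0.6, n_discard=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
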