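import numpy as np
import pytest

from crispritools.simulate import ColonySimConfig, simulate_colony


@pytest.fixture(scope="session")
def colony_noiseless():
    """A small clean microcolony movie (no shot noise, faint background noise)."""
    cfg = ColonySimConfig(
        seed=11, n_frames=22, shot_noise_sd=0.0, background_sd=1.0
    )
    movie, truth = simulate_colony(cfg)
    return cfg, movie, truth


@pytest.fixture(scope="session")
def colony_knockdown():
    """Complete knockdown (r = 0) with onset early in the movie."""
    cfg = ColonySimConfig(
        seed=7,
        n_frames=20,
        induction_time=0.0,
        quiescent_delay=0.6,
        residual_synthesis=0.0,
        shot_noise_sd=0.0,
        background_sd=1.0,
    )
    movie, truth = simulate_colony(cfg)
    return cfg, movie, truth
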