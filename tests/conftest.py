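import numpy as np
import pytest

from hierkit import synthio


@pytest.fixture
def quartet_world():
    """Strongly ordered latent hierarchy in a group of four."""
    return synthio.DominanceWorld(
        animal_ids=["m1", "m2", "m3", "m4"],
        latent_dominance=[1.5, 0.5, -0.5, -1.5],
        steepness=3.0,
        upset_rate=0.0,
        seed=11,
    )


@pytest.fixture
def quartet_log(quartet_world):
    return synthio.simulate_tournament(quartet_world, n_round_robins=14)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
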