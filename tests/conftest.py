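import numpy as np
import pytest

from srnav.grid import World
from srnav.worldgen import GeneratorParams, Paradigm, generate_task


@pytest.fixture
def empty_world() -> World:
    return World.empty(20, 20)


@pytest.fixture
def small_world() -> World:
    """8x8 world (6x6 interior) with a couple of obstacle cells."""
    w = World.empty(8, 8, reward_cell=(6, 1))
    w.cells[4, 3] = 1  # BARRIER at (3, 4)
    w.cells[2, 4] = 1  # BARRIER at (4, 2)
    return w


@pytest.fixture
def main_task():
    params = GeneratorParams(paradigm=Paradigm.MAIN)
    rng = np.random.default_rng(np.random.SeedSequence([7, 5]))
    return generate_task(params, rng, episodes_per_world=10)
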