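import numpy as np
import pytest

from landflat import EnergyMatrix, FixtureSpec, SequenceSpace, generate_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_pos_space():
    """Two mutable positions, two types each, two rotamers."""
    return SequenceSpace([1, 2], [["A", "C"], ["A", "C"]], 2)


@pytest.fixture
def toy_spec():
    return FixtureSpec(n_positions=3, types_per_position=4,
                       rotamers_per_type=2, energy_scale=1.0,
                       pair_density=0.3, seed=42)


@pytest.fixture
def toy_pair(toy_spec):
    return generate_pair(toy_spec)


@pytest.fixture
def toy_apo(toy_pair):
    return toy_pair[0]


def brute_force_total(matrix, state):
    """Literal loop-over-all-pairs recomputation (test oracle)."""
    positions = matrix.space.all_positions
    e = 0.0
    for pos in positions:
        e += matrix.diag_energy(pos, state.type_at[pos], state.rotamer_at[pos])
    for a, i in enumerate(positions):
        for j in positions[a + 1:]:
            e += matrix.pair_energy(
                i, state.type_at[i], state.rotamer_at[i],
                j, state.type_at[j], state.rotamer_at[j],
            )
    return e
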