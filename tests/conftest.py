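import numpy as np
import pytest

from connectotype import (
    ConnectomeMatrix,
    Parcellation,
    PopulationSpec,
    generate_population,
)
from connectotype.parcellation import default_fine_parcellation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_system_parc():
    return Parcellation("toy", ("S", "S", "T", "T"))


def random_connectome(n, rng, parc=None, density=1.0, subject_id="rand"):
    """Random symmetric nonnegative SC matrix with zero diagonal."""
    W = rng.random((n, n))
    if density < 1.0:
        W[rng.random((n, n)) > density] = 0.0
    W = np.triu(W, 1)
    W = W + W.T
    if parc is None:
        parc = Parcellation("rand", tuple(f"n{i}" for i in range(n)))
    return ConnectomeMatrix(subject_id, parc, W)


@pytest.fixture(scope="session")
def small_population():
    """Calibrated synthetic population, one sex, 10 subjects per archetype,
    48-node fine scheme — shared by clustering/dynamics/lesioning tests."""
    spec = PopulationSpec(
        n_per_group=10,
        sexes=("male",),
        fine_parcellation=default_fine_parcellation(48),
        seed=11,
    )
    subjects, labels = generate_population(spec)
    return spec, subjects, labels
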