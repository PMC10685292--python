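import numpy as np
import pytest
from hypothesis import settings

import superplan as spn

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_grid():
    return spn.VoxelGrid()


@pytest.fixture(scope="session")
def phantom_structures(default_grid):
    return spn.build_phantom(default_grid)


@pytest.fixture(scope="session")
def phantom_problem():
    """The packaged feasible horseshoe-phantom planning problem."""
    return spn.make_phantom_problem()


@pytest.fixture(scope="session")
def phantom_objective(phantom_problem):
    """Target/core/body objective set shaped like the benchmark table."""
    specs = [
        spn.ObjectiveSpec("sq_deviation", "Target", 1000.0, 60.0),
        spn.ObjectiveSpec("sq_overdose", "Core", 100.0, 20.0),
        spn.ObjectiveSpec("sq_overdose", "Body", 30.0, 30.0),
    ]
    return spn.CompositeObjective(specs, phantom_problem.structures,
                                  phantom_problem.matrix)


def feasible_toy(seed: int) -> spn.ToyFeasibilityProblem:
    return spn.make_toy_problem(n=200, m=30, density=0.1, feasible=True,
                                slack=0.5, seed=seed)


def toy_constraints(toy: spn.ToyFeasibilityProblem) -> spn.ConstraintSystem:
    return spn.ConstraintSystem.from_bounds(toy.lower, toy.upper,
                                            matrix=toy.matrix)


@pytest.fixture(scope="session")
def toy_problems():
    return {seed: feasible_toy(seed) for seed in range(10)}
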