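import numpy as np
import pytest

from floraplan import synthgeo
from floraplan.planning_io import (
    AmountMatrix,
    ConservationProblem,
    PlanningGrid,
    TargetSpec,
)


@pytest.fixture(scope="session")
def env40():
    """A 40x40 landscape shared by fast unit tests."""
    return synthgeo.make_landscape(40, 40, seed=7)


@pytest.fixture(scope="session")
def species12(env40):
    return synthgeo.simulate_species(env40, n_species=12, seed=2)


@pytest.fixture(scope="session")
def default_study():
    """One full default-study run (seeded), shared by the end-to-end checks."""
    from floraplan.pipeline import run_default_study

    return run_default_study(seed=0)


def make_random_problem(
    rng: np.random.Generator,
    n_rows: int = 3,
    n_cols: int = 4,
    n_species: int = 4,
    blm: float = 0.01,
    prop: float = 0.3,
    spf: float = 50.0,
    density: float = 0.4,
) -> ConservationProblem:
    """Small random reserve-selection instance for oracle comparisons."""
    n_pu = n_rows * n_cols
    counts = (rng.random((n_species, n_pu)) < density) * rng.integers(
        1, 40, (n_species, n_pu)
    )
    # every species needs some range
    for s in range(n_species):
        if counts[s].sum() == 0:
            counts[s, rng.integers(n_pu)] = rng.integers(1, 40)
    grid = PlanningGrid(n_rows=n_rows, n_cols=n_cols, pu_side_km=2.0, cost=None, status=None)
    amounts = AmountMatrix(
        species_ids=[f"s{i}" for i in range(n_species)],
        cell_counts=counts,
        cell_area=0.1,
    )
    targets = TargetSpec.uniform(n_species, prop, spf=spf)
    return ConservationProblem(grid=grid, amounts=amounts, targets=targets, blm=blm)
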