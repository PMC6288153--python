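import numpy as np
import pytest

from scnlme import (
    CellData,
    CellParameters,
    default_grid,
    paper_like_design,
    simulate_dataset,
    simulate_observable,
)


@pytest.fixture(scope="session")
def grid181():
    return default_grid()


@pytest.fixture
def model_i_params():
    return CellParameters({"delta": 0.2, "gamma": 1.1, "kappa": 80.0, "t0": 1.0, "offset": 8.0})


def random_model_i_params(rng, t_max=30.0):
    """Random positive model (i) parameters spanning realistic trajectories."""
    return CellParameters(
        {
            "delta": float(rng.uniform(0.05, 1.5)),
            "gamma": float(rng.uniform(0.02, 1.5)),
            "kappa": float(np.exp(rng.uniform(np.log(5.0), np.log(500.0)))),
            "t0": float(rng.uniform(0.2, min(4.0, t_max / 2))),
            "offset": float(np.exp(rng.uniform(np.log(1.0), np.log(30.0)))),
        }
    )


def make_cell(params, times, sigma=0.0, rng=None, cell_id="c0", experiment="eGFP", replicate="r1"):
    """One synthetic cell from given model (i) parameters."""
    y = simulate_observable("i", params, times)
    if sigma > 0:
        y = y + rng.normal(scale=sigma, size=times.size)
    return CellData(cell_id=cell_id, experiment=experiment, replicate=replicate, times=times, y_obs=y)


@pytest.fixture(scope="session")
def two_construct_dataset():
    """Desk-scale two-construct dataset with truth, shared across tests."""
    pop, exp = paper_like_design(n_cells_per_experiment=50)
    dataset, truth = simulate_dataset(pop, exp, seed=11)
    return pop, exp, dataset, truth
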