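import numpy as np
import pandas as pd
import pytest

from camsdm.grid import GridSpec, RasterLayer, RasterStack
from camsdm.modeling import LearnerSpec, ModelRun, fit_and_score
from camsdm.pipeline import ScenarioConfig, run_scenario
from camsdm.synthetic import default_landscape


@pytest.fixture(scope="session")
def landscape():
    """The canonical synthetic study system (64x64 grid, 500 biased presences)."""
    return default_landscape(seed=1)


@pytest.fixture(scope="session")
def recovery_report(landscape):
    """One scaled scenario-1 run (2 algorithms x 2 PA x 2 repeats), shared
    across the tests that check niche recovery and ensemble behaviour."""
    cfg = ScenarioConfig.for_scenario(
        1, species="synthetic", n_pa_realizations=2, n_repeats=2, master_seed=7
    )
    return run_scenario(cfg, landscape.stack, landscape.occurrences)


def small_grid(n_rows=4, n_cols=5, lon0=0.0, lat0=10.0, cell=1.0):
    return GridSpec(n_rows=n_rows, n_cols=n_cols, lon_origin=lon0, lat_origin=lat0, cell_size=cell)


@pytest.fixture
def grid():
    return small_grid()


def layer_of(grid, values, name="layer"):
    return RasterLayer(grid, np.asarray(values, dtype=float), name)


def constant_layer(grid, value, name="const"):
    return RasterLayer(grid, np.full(grid.shape, float(value)), name)


@pytest.fixture(scope="session")
def toy_ensemble():
    """Two fitted runs on a separable toy problem where only x1 matters.

    x2 is constant in the table, so no tree can split on it: its
    permutation importance is exactly zero.
    """
    rng = np.random.default_rng(42)
    n = 150
    x1 = rng.normal(0, 1, 2 * n)
    label = (x1 > 0).astype(int)
    table = pd.DataFrame(
        {
            "lon": rng.uniform(0, 5, 2 * n),
            "lat": rng.uniform(5, 10, 2 * n),
            "label": label,
            "x1": x1,
            "x2": np.zeros(2 * n),
        }
    )
    members = []
    for i, algo in enumerate(("boosted_trees", "random_forest")):
        run = ModelRun(
            learner=LearnerSpec(algorithm=algo, seed=i, hyperparameters={"n_estimators": 50}),
            pa_index=1,
            repeat_index=i + 1,
        )
        fit_and_score(run, table, split_seed=i)
        members.append(run)
    return members, table
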